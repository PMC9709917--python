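"""Serialization of pipeline artifacts.

Spherical maps are stored as an ``.npz`` archive holding the 9 x n_pix channel
array, the miss mask, and a JSON header (n_side, ordering, channel names, miss
count).  Sphere sets and vertex property tables are plain TSV; labels, pair
lists, splits and metrics use TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import CHANNEL_NAMES, SphericalMaps
from .pocket import PocketSpheres
from .properties import VertexProperties

__all__ = [
    "save_maps", "load_maps", "save_spheres", "load_spheres",
    "save_vertex_properties", "load_vertex_properties",
    "read_class_labels", "read_pair_labels", "save_split", "load_split",
    "save_metrics",
]


def save_maps(maps: SphericalMaps, path) -> None:
    header = {
        "n_side": maps.n_side,
        "ordering": "nested",
        "channels": list(CHANNEL_NAMES),
        "n_miss": int(maps.miss_mask.sum()),
    }
    np.savez(str(path), channels=maps.channels, miss_mask=maps.miss_mask,
             header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))


def load_maps(path) -> SphericalMaps:
    with np.load(str(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        return SphericalMaps(channels=data["channels"],
                             miss_mask=data["miss_mask"],
                             n_side=int(header["n_side"]))


def save_spheres(spheres: PocketSpheres, path) -> None:
    df = pd.DataFrame({
        "x": spheres.centers[:, 0], "y": spheres.centers[:, 1],
        "z": spheres.centers[:, 2], "r": spheres.radii,
        "cluster": spheres.cluster_id})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_spheres(path) -> PocketSpheres:
    df = pd.read_csv(path, sep="\t")
    return PocketSpheres(df[["x", "y", "z"]].to_numpy(), df["r"].to_numpy(),
                         df["cluster"].to_numpy(int))


def save_vertex_properties(props: VertexProperties, path) -> None:
    df = pd.DataFrame({
        "vertex": np.arange(len(props.hydrophobicity)),
        "DON": props.pseudo[:, 0], "ACC": props.pseudo[:, 1],
        "ALI": props.pseudo[:, 2], "ARO": props.pseudo[:, 3],
        "hydrophobicity": props.hydrophobicity, "charge": props.charge})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_vertex_properties(path) -> VertexProperties:
    df = pd.read_csv(path, sep="\t")
    return VertexProperties(
        pseudo=df[["DON", "ACC", "ALI", "ARO"]].to_numpy(np.int8),
        hydrophobicity=df["hydrophobicity"].to_numpy(),
        charge=df["charge"].to_numpy())


def read_class_labels(path):
    """TSV (pocket_id, class) -> (ids array, labels array)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["pocket_id", "class"],
                     comment="#")
    return df["pocket_id"].to_numpy(), df["class"].to_numpy()


def read_pair_labels(path):
    """TSV (id_a, id_b, label) -> list of tuples."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["id_a", "id_b", "label"], comment="#")
    return list(df.itertuples(index=False, name=None))


def save_split(is_test: np.ndarray, path) -> None:
    Path(path).write_text(json.dumps(
        {"test_ids": np.flatnonzero(is_test).tolist(),
         "n_items": int(len(is_test))}))


def load_split(path) -> np.ndarray:
    d = json.loads(Path(path).read_text())
    out = np.zeros(d["n_items"], bool)
    out[d["test_ids"]] = True
    return out


def save_metrics(metrics: dict, path) -> None:
    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    Path(path).write_text(json.dumps(clean(metrics), indent=1))
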
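# Methods

This note records the models, numerical choices, and limitations behind
`pocketsphere`, in the order the pipeline runs.

## Pocket imprint

**Gap spheres.** For every protein atom pair whose inter-surface gap
`g = d − R_a − R_b` lies in `[2·r_min, 2·r_max]`, a trial sphere of radius
`g/2` is centered midway along the gap. If the trial sphere penetrates another
atom's van der Waals sphere, it is moved away from the worst intruder by half
the penetration depth and shrunk by the same amount (leaving it exactly
tangent), for at most 10 iterations; spheres that end below `r_min` or still
penetrate are discarded. Defaults `r_min = 1.0 Å`, `r_max = 4.0 Å`, pair
cutoff 12 Å are the published SURFNET operating point. Near-coincident
spheres are deduplicated on a 0.75 Å grid (largest radius kept per cell);
this is a discretization of the classic grid-based construction and changes
the imprint negligibly while keeping sphere counts tractable. Overlapping
spheres form clusters via connected components; each cluster is a candidate
cavity.

**Binding-site filter.** With a bound ligand, the site is the set of protein
atoms within `r = 6 Å` of any ligand heavy atom (the union over an aligned
ligand ensemble if several poses are given); without one, a pluggable
predictor supplies the atom set (built-in default: atoms within `r` of the
largest sphere cluster's centers). Spheres are kept iff their *center* lies
inside the closed convex hull of the selected atoms; the center convention is
ours, since no partial-overlap rule is standard.

**Surface.** The solvent-excluded surface of the sphere union is extracted as
the marching-cubes iso-surface, at level `−probe`, of the signed distance to
the probe-inflated union `F(x) = min_i(|x−c_i| − r_i − probe)`. This is this
package's surface algorithm (closed-source molecular-surface tools are
avoided); it preserves the probe-radius contract and rounds re-entrant
grooves with curvature ~`probe`. The requested triangulation density sets the
grid spacing via the measured marching-cubes yield of ≈1.7 vertices per
spacing² of surface; the achieved density stays within a factor 2 of the
request. Cleanup removes non-finite vertices, degenerate and duplicate faces,
and unreferenced vertices (vertex order preserved; idempotent). Smoothing is
uniform (umbrella-weight) Laplacian averaging of the 1-ring, 4 iterations by
default; weights are unspecified in the underlying construction, and uniform
weights are the simplest choice.

## Vertex properties

**Pseudocenters.** Functional groups are summarized by five center kinds:
donor (DON), acceptor (ACC), mixed donor/acceptor (DAC), aliphatic (ALI),
aromatic/π (ARO). Backbone rules are built in (amide N → DON with direction
bisecting C(prev)–N–Cα; carbonyl O → ACC along C=O); side-chain rules ship as
an editable TSV following CavBase-style conventions, including a minimal
template set for the synthetic pseudo-residues. The ARO ring normal's sign is
intrinsic (cross product of the first ring edges in template atom order), so
property assignment is equivariant under proper rigid motions; a reflection
would flip it, which we accept, as chiral structures are never mirrored in
this pipeline.

**Exposure filtering.** Each center's exposure vector `r` is the normalized
sum of vectors to mesh vertices within `d_max = 3 Å`. A center survives iff
the angle between its interaction direction `v` and `r` is at most 100°
(DON/ACC/ARO) or 120° (DAC); ALI centers are isotropic and never filtered;
non-ALI centers with undefined `r` (no nearby surface, or exact cancellation)
are dropped. Angles are `arccos` of the clamped dot product, in degrees.

**Vertex encoding.** Each vertex takes the channels of its single nearest
surviving center within 3 Å — DAC sets both DON and ACC bits — else stays
NULL (all-zero), modelling pocket-mouth vertices with no lining chemistry.

**Hydrophobicity.** Atoms are binarized by partial-charge magnitude
(|q| ≤ 0.25 e → −1 nonpolar, |q| > 0.25 e → +1 polar; the threshold is applied
to |q| since negative partial charges are as polar as positive ones) and
averaged over atoms within 4.5 Å with inverse-distance weights floored at
0.5 Å. The floor keeps single-atom dominance bounded; the weighted average of
±1 values is in [−1, 1] by convexity.

**Electrostatics.** Vertex potentials come either from an external OpenDX
scalar grid (trilinear interpolation; the grid must cover the mesh) or from
the built-in screened-Coulomb backend
`φ(x) = C Σ_i q_i e^{−κ d_i}/(ε_r d_i)` with κ = 0.1 Å⁻¹, ε_r = 4, C chosen so
φ is in kT/e at 298 K. The ±30 cap is interpreted in kT/e — the customary
output unit of Poisson–Boltzmann solvers, which makes the cap meaningful —
then scaled to [−1, 1].

## Spherical maps

The mesh is centered on its vertex centroid and scaled so the farthest vertex
sits at radius 0.99 (not 1.0, so rays never start on the surface). One ray
per nested-HEALPix pixel runs from the pixel's unit vector to the origin;
the first triangle hit gives depth (distance traveled from the sphere,
clamped to [0, 1]), cos/sin of the angle between the outward face normal and
the hit→pixel direction (a concentric sphere reads cos = 1 everywhere;
sin ≥ 0 makes the pair redundant but both normal maps are kept deliberately),
the mean of the three face-vertex values for charge and hydrophobicity, and
the OR of the face-vertex bits for the binary channels. Pixels whose segment
crosses no triangle — open pocket mouths — carry zeros and a miss flag:
"far and featureless", matching the NULL-vertex intent. Ray casting is
vectorized Möller–Trumbore over candidate pairs after an exact spherical-cone
culling (every ray is a radius through the origin, so a triangle is hittable
only from directions inside its projected cone or the antipode).

HEALPix (nested ordering only) is implemented in-package from the standard
pixelization algorithm and validated against the analytically known base
pixel centers plus structural invariants; nested ordering is mandatory
because the 4:1 pooling contract identifies the children of pixel `p` with
pixels `4p..4p+3` at doubled N_side.

## Network

Graphs are rebuilt independently at each pooled resolution (N_side 16, 8, 4,
2) with k = 20 chordal nearest neighbors (k clipped to n_pix − 1 at the
coarsest levels), Gaussian weights `exp(−d²/4t)`, union symmetrization, and
`t` defaulting to a quarter of the mean squared k-th-neighbor distance (the
DeepSphere rule; overridable per level). The convolution is the monomial
polynomial `y = Σ_{k≤3} L^k x a_k`, evaluated by recursive sparse
applications of `L` (a Chebyshev basis is deliberately not used; the printed
equation is implemented as stated).

Two numerical choices matter in practice and are ours:

* **Coefficient reparameterization.** Trainable parameters are
  `â_k = a_k · λ_max^k` (λ_max the largest Laplacian eigenvalue, deterministic
  Lanczos with a 2·max-degree fallback). The model class is identical —
  `GraphConv.coeffs` exposes the effective `a_k` — but without this the
  monomial basis is so ill-conditioned (L³ amplifies high graph frequencies
  by λ_max³ ≈ 10³–10⁴) that the standard learning rate of 0.05 oscillates and
  desk-scale training stalls near 72% training accuracy; with it the same
  recipe converges to 100%.
* **Embedder head scale.** The final dense layer of the embedding head is
  initialized 10× below He scale so that initial pair distances sit at the
  margin scale m = 1.0. With standard initialization, initial distances are
  ~10 m: the hinge term is silent, positives dominate, and contrastive
  convergence is an order of magnitude slower than the desk-scale epoch
  budget.

Batch normalization uses per-channel statistics over batch and pixels,
momentum 0.9 running averages in eval mode. Layer pooling is max over nested
4-blocks; global pooling is the average over the 12 base pixels, which is
what makes the output exactly invariant to any signal permutation the
rotation group induces up to resampling error.

## Synthetic data

The fixture generator stands in for crystallographic input at desk scale.

* `make_toy_protein` places pseudo-residues (donor / acceptor / aromatic /
  aliphatic / charged± templates of 2–6 atoms) on a Fibonacci-spaced shell of
  the requested cavity radius, interaction directions facing the cavity
  center, with a mouth opening of the requested angle around +z and a dummy
  tetrahedral ligand inside (sized so the 6 Å selection always reaches the
  lining). Lining fractions are realized exactly by largest-remainder
  apportionment. It emulates concavity, lining chemistry, and
  ligand-occupancy — not real side-chain rotamers, backbone connectivity,
  crystallographic noise, or solvent. Passing tests therefore demonstrate
  the pipeline's internal consistency on idealized cavities, not performance
  on PDB structures.
* `make_map_dataset` skips geometry: each class is a fixed set of
  spherical-cap motifs on chosen channels, each sample an independently
  rotated, noise-perturbed rendering, so class identity is orientation-free
  by construction. Restricting motifs to one channel creates classes that are
  invisible to the remaining channels (feature-ablation fixtures).
* `SmoothPocketMaps` is a band-limited map-space pocket (Gaussian caps on the
  continuous channels only) that can be rendered *exactly* under any
  rotation. It is the reference input for quantifying rotation equivariance,
  because discontinuous binary channels alias at pixel boundaries no matter
  the architecture.

## Measured rotation invariance

Median relative L2 change of the 256-d descriptor over 20 smooth synthetic
pockets × 100 uniform rotations:

* augmentation-trained embedder: ≈ 1.3–1.8% (the accepted quantity — rotation
  invariance is a property the training procedure enforces, so the trained
  model is the object of the claim);
* random-initialization network on the same smooth pockets: ≈ 4–6%;
* random-initialization network on full-pipeline toy-protein pockets: ≈ 12%,
  dominated by pixel-level aliasing of the spotty binary pseudocenter
  channels (their map-level change under rotation is 16–24%, vs 2–4% for the
  smooth channels).

The last figure is a real limitation: isolated functional-group patches near
one pixel in size cannot be projected rotation-stably at N_side = 16.
Training with rotation augmentation (as both objectives do) teaches the
filters to pool over that flicker.

## Desk-scale problem sizes

Sanity training uses 60 maps (3 balanced classes) at N_side = 16 with the
full 32/64/128/256 architecture: the classifier is checked on one stratified
fold for 30 epochs; the embedder trains on 128 sampled pairs per epoch for 10
epochs against a pocket-level train/test split. These sizes are the package's
standard demonstration conditions; the training recipes themselves (learning
rates, decay, batch sizes, margin, augmentation, cluster-respecting splits)
are the full-scale ones.

## Known limitations

* The imprint surface is an iso-surface approximation of the solvent-excluded
  surface; sharp sphere-intersection seams are rounded at the grid scale.
* Ray casting records only the first intersection: non-star-shaped pockets
  lose information behind the first wall.
* Hydrophobicity uses the binarized-charge scale described above, not a
  calibrated atomic hydrophobicity scale.
* The built-in screened-Coulomb potential is a Debye-Hückel surrogate, not a
  Poisson–Boltzmann solution; external OpenDX grids should be supplied when
  fidelity matters.
* Sequence identity for split construction is consumed as a precomputed
  matrix; the built-in 3-mer fallback is a coarse stand-in for an aligner.
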
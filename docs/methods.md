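# Methods

This note documents the models, defaults and numerical choices behind
embryoquant, and what the synthetic phantoms do and do not establish about
real data.

## Embryo phantoms

The phantom emulates a fixed multi-channel confocal stack of a
cleavage-stage embryo.  Cells are laid out as a **power diagram** (Laguerre
tessellation) over a spherical embryo: seeds for outer cells sit on a
Fibonacci-sphere shell (randomly rotated and jittered per seed), designated
inner cells sit at or near the centre, and every voxel inside the embryo
ball is assigned to the cell minimising ‖v − cᵢ‖² − rᵢ².  This partition has
no gaps, which is what makes the inner/outer ground truth exact: an inner
cell genuinely has no voxel face-adjacent to the medium.  The generator
*verifies* both directions (inner cells enclosed, all other cells touching
the medium) and raises a `PackingError` naming the offending cells when a
requested configuration is geometrically infeasible — infeasible
configurations are rejected, never silently adjusted.

Each nucleus is a sphere (optionally wrinkled, below) placed at its cell's
incentre — the interior point of maximal clearance from the cell boundary,
found on a padded per-cell distance transform — with radius
`nucleus_radius_fraction × cell radius`.  The lamina is painted as a radial
band of width `lamina_thickness` at intensity `ratio × B` over a nucleoplasm
at intensity `B`, so the mean-intensity ratio over the true masks equals the
requested L:N exactly (to float precision) before noise.

Default imaging conditions, chosen once as typical for confocal imaging of
mouse embryos and used throughout the tests:

| parameter | default | why |
|---|---|---|
| voxel spacing | (1.0, 0.5, 0.5) µm (z, y, x) | anisotropic on purpose: all downstream code must honour physical units |
| embryo radius | 25 µm | 8-cell mouse embryo scale |
| cell radius | 12 ± 1 µm | blastomere scale at that stage |
| nucleus radius fraction | 0.45 | ≈ 11 µm nuclear diameter |
| lamina width | 1.2 µm | a thin lamina rim blurred by a ~0.5 µm lateral PSF |
| intensities | nucleoplasm/DAPI 100, cortex 200, cytoplasmic mesh 40 | bright interfaces over a dim meshwork |
| noise | Poisson (scale 2) + Gaussian (SD 5) | shot + read noise; nucleoplasm SNR ≈ 20; both independently switchable |

The membrane/F-actin channel paints every label-interface voxel (one voxel
deep on each side of a boundary) at the cortical intensity, so a ±1 µm
erosion clears it from the cytoplasm mask, plus a Gaussian-smoothed random
speckle texture in each cell's cytoplasm scaled so its *mean* equals that
cell's requested meshwork density — densities are therefore recovered
exactly on noiseless truth masks.

**Wrinkling** is a real spherical-harmonic radial perturbation
r(θ, φ) = R (1 + a·Ỹ_l^m(θ, φ)) with Ỹ scaled to unit peak amplitude
(degree l configurable, order m = min(2, l)).  The same analytic surface is
exposed as a point-cloud sampler (`wrinkled_sphere_cloud`) so geometric
estimators can be checked against the exact surface.

**What the phantom does not emulate:** PSF blurring of structures other than
the (implicitly widened) lamina rim, spectral bleed-through, intensity decay
with depth, mitotic figures, cell-shape anisotropy beyond what the power
diagram produces, or temporal dynamics.  Passing tests therefore demonstrate
correctness of the *measurement* pipeline under realistic noise and
geometry, not robustness to every artefact of real microscopy.

## Segmentation

Nuclei: Gaussian smoothing (physical σ, default 0.75 µm) → threshold → hole
filling → distance-transform watershed split → physical size filter.  The
default threshold is the **half-max (FWHM) criterion**, midway between the
background level (volume median) and the foreground plateau (99.9th
percentile).  Otsu is available but not the default: with a dominant
background class its threshold falls well below the 50% edge level and
biases boundaries outward by ~0.1–0.2 µm, which measurably contaminates the
L:N shell.  The smoothing σ trades boundary-localization bias (a curvature
bias of order σ²/R pulls boundaries inward) against noise robustness;
0.75 µm keeps noiseless boundary Jaccard ≥ 0.9 while preserving L:N
accuracy.

Cells: nucleus-seeded watershed on the smoothed membrane channel, restricted
to an embryo foreground mask (Otsu on the membrane channel ∪ nuclei, closed
and hole-filled, seed-connected components only).  The watershed is
**compact** (default compactness 0.5): with plain intensity-ordered
flooding, a neighbour's basin can wrap a voxel-thin layer over another
cell's outer surface along the bright embryo rim, sealing it off and
corrupting inner/outer classification; the distance penalty eliminates this.

Compartments: all erosions/dilations threshold an anisotropic Euclidean
distance transform, so band widths are honoured in µm on any grid.  The
lamina shell default is **1.2 µm**: the measurement shell should cover the
full lamina signal width so that the nucleoplasm reference region stays
uncontaminated — lamina signal leaking into the nucleoplasm mean compresses
high ratios far more than nucleoplasm signal diluting the shell mean.  The
accuracy limit of the whole L:N path is the axial voxel quantization of the
erosion depth (±half a z-voxel), visible as a few-percent compression at
high ratios.  Cortex/cytoplasm use the ±1 µm band construction (dilated
minus eroded; eroded minus nucleus), with band = 0 degenerating to an empty
cortex.  Inner/outer classification uses strict 6-connectivity face
adjacency to the border-connected background component, so internal
cavities never count as "outside".

## Geometry

- Surface point clouds are boundary-voxel centres (µm); voxel centres sit at
  (index + 0.5) × spacing from the volume corner.
- The apical surface deletes points nearer than `cutoff_um` (default 1.0 µm,
  a deliberate choice — points at exactly the cutoff are retained) to any
  neighbouring cell's points.
- Apical area: the free-boundary facets of a 3D Delaunay tetrahedralization
  of the cell cloud are its convex-hull triangles; the apical area sums
  those whose three vertices are all apical.  Near-coplanar clouds fall back
  to a planar Delaunay triangulation in the best-fit plane.
- The oriented box aligns ẑ with (apical CM − embryo CM) (falling back to
  the cell centroid for fully internalized cells, recorded per cell) and
  minimizes the in-plane footprint over a 0.25° rotation grid with bounded
  refinement; verified against a 0.05° brute-force search.
- The ellipsoid fit is the least-squares algebraic quadric constrained to a
  real ellipsoid, computed in centred coordinates (the algebraic
  normalization is origin-dependent; centring makes the fit invariant under
  rigid motion).  A minimum-volume enclosing ellipsoid was deliberately not
  used: it touches only the outermost bumps of a wrinkled surface and biases
  the deformation index directionally.
- The deformation index measures point-to-ellipsoid distance **radially**
  (along the centre→point ray), matching its normalization by the distance
  to the centre; it is checked against per-point root-finding of the
  ray-ellipsoid intersection.
- Sphericity uses the voxel-count volume and the area of a marching-cubes
  mesh of the mask smoothed by one voxel (raw binary marching cubes
  overestimates area by staircase facets); values may slightly exceed 1 on
  coarse grids.
- Mean curvature is the cotangent-Laplacian estimator (|Lx| / 2A with
  one-third barycentric vertex areas), signed by the outward normal
  (orientation fixed via the mesh's signed volume).  Its per-vertex SD
  serves as a surface-irregularity score.

## FRAP

r(t) = (roi − bg) / (ref − bg) removes background and multiplicative
photofade; double normalization maps the pre-bleach mean to 1 and the first
post-bleach frame to 0 (the bleach frame itself is included in the fit as
the y = 0 anchor).  The single-exponential fit is deterministically
initialized (I∞₀ = mean of the last 10% of frames; τ₀ = time to half of
I∞₀), bounded (τ ≤ 100 × the post-bleach duration, bound hits flagged),
and reports RMSE; the immobile fraction is 1 − I∞ exactly.  A
double-exponential was considered and rejected as the default: the single
exponential is the minimal model, and the generator produces single-
exponential truth.

## Statistics

Routing is a pure function of the D'Agostino-Pearson p-values (α = 0.05)
and the group count; groups with n < 8 (below the omnibus test's validity)
route directly to the non-parametric branch and are flagged.  Mann-Whitney
uses exact enumeration of mid-rank splits (valid under ties) for samples up
to n = 10 per group and the tie-corrected normal approximation beyond.
Dunn's post-hoc z-tests use pooled mid-ranks with tie correction and
Bonferroni adjustment.  Quartiles use linear interpolation (so {1,2,3,4}
gives median 2.5, IQR 1.5).  No multiplicity correction is applied across
different metrics, only within multi-group post-hocs.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use two-cell phantoms
(embryo radius 16 µm) for the L:N recovery grid (4 ratios × 10 seeds),
coarse-grid (2 × 1 × 1 µm, ≤ 64³) 8–16-cell phantoms for the twenty
classification checks, and a single 16-cell embryo (radius 32 µm, three
inner cells) for the end-to-end inner-vs-outer comparison — sizes chosen so
the full validation completes in minutes on one CPU while every code path
(anisotropy, packing, enclosure, noise) is exercised.

## Known limitations

- L:N accuracy degrades when the lamina signal width differs substantially
  from the configured shell thickness; the shell is a config parameter and
  should be matched to the data's apparent rim width.
- The apical-area estimator assumes cells are convex enough that hull
  facets approximate their free surface; strongly concave cells would need
  an alpha-shape variant.
- Sub-voxel nuclei displacements and axial quantization bound compartment
  accuracy at ~half a z-voxel; prefer ≤ 1 µm axial sampling.
- `sphericity` and `local_mean_curvature` operate on smoothed
  marching-cubes meshes; per-vertex curvature on such meshes is noisy and
  only distributional summaries should be interpreted.
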
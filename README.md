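# embryoquant

3D image quantification of nuclear lamina mechanics in preimplantation
embryos: subnuclear **lamina : nucleoplasm (L:N) ratiometry**, cortex and
cytoplasm compartment masks, cell and nucleus morphometrics, FRAP
immobile-fraction analysis, and normality-routed statistics — with a
synthetic embryo-phantom generator so the whole pipeline is testable against
known ground truth.

## Who this is for

Groups quantifying confocal stacks of cleavage-stage embryos (or comparable
multicellular aggregates) who need reproducible, scriptable versions of
measurements that are usually done interactively: how enriched a Lamin
channel is at the nuclear periphery, whether a blastomere touches the outside
medium (inner vs outer cells), how flat or radially elongated a cell is, how
wrinkled its nucleus is, and what fraction of a photobleached protein pool
never recovers.

## The core quantities

For each nucleus the lamina shell of physical thickness *t* (default 1.2 µm)
is carved off by an anisotropic Euclidean distance transform and

&nbsp;&nbsp;&nbsp;&nbsp;L:N = mean I(lamina shell) / mean I(nucleoplasm),

the readout of lamina enrichment of Lamin A/C.  Each cell is additionally
eroded/dilated by ±1 µm to define cytoplasm and cortex masks, and every
channel is reported as a DAPI-standardized mean over each compartment.

Cell shape uses a radially oriented minimal bounding box, with the local z
axis pointing from the embryo's centre of mass to the centre of mass of the
cell's apical (contact-free) surface:

- aspect ratio = (Lz − max(Lx, Ly)) / (Lz + max(Lx, Ly)), in (−1, 1);
- flatness = Lz_api / Lz, in [0, 1];
- apical surface area from Delaunay free-boundary facets of the exported
  surface point cloud;
- nuclear deformation index = mean over surface points of the radial
  distance to the least-squares ellipsoid fit, normalized by the distance to
  the ellipsoid centre (0 for a perfect ellipsoid);
- sphericity Ψ = π^⅓ (6V)^⅔ / A.

FRAP traces are background-corrected, normalized to an unbleached reference,
double-normalized (pre-bleach mean = 1, first post-bleach frame = 0) and
fitted with y(t) = I∞ (1 − e^{−(t−t₀)/τ}); the **immobile fraction is
1 − I∞**.

Group comparisons follow a normality-routed scheme: D'Agostino–Pearson on
every group, then t-test / ANOVA+Dunnett if all pass, otherwise
Mann-Whitney U (exact, tie-aware, for small samples) / Kruskal-Wallis+Dunn.

## Worked example

No public imaging data accompanies the study design this package supports,
so the executable tutorial generates a 16-cell embryo phantom in which three
fully enclosed inner cells are built with a true L:N of 1.2 against 2.0 for
the thirteen outer cells, then runs segmentation → quantification →
geometry → statistics:

```bash
embryoquant pipeline demo --seed 0 --out demo-run
```

prints

```
analyzed 16 cells; median L:N by class:
position_class
inner    1.184826
outer    1.934295
routed test: mann-whitney, p = 0.01058
outputs in demo-run
```

The recovered medians sit within a few percent of the built-in truth (1.2
and 2.0), the three inner cells are identified exactly from voxel adjacency
to the outside medium, and the routed two-group test (Mann-Whitney here,
because n = 3 inner cells is below the minimum for the omnibus normality
test) rejects at p ≈ 0.011.  `demo-run/` contains `records.csv` (one row
per cell with every metric), `geometry.csv`, `report.json` and
`provenance.json` (all parameters and seeds; re-running the same
provenance reproduces the outputs bit-identically).

The same stages are available individually — `embryoquant phantom make`,
`segment`, `quantify`, `report`, `frap fit` — and as library functions
(`embryoquant.run_pipeline`, `embryoquant.ln_ratio`, ...).

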
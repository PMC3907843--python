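# stromspat

Microspatial quantification of sulfate-reducing microorganisms (SRM) in
stromatolite surface-mat micrographs.

## The problem

Bahamian stromatolite surface mats cycle between a non-lithifying,
accreting state (**Type-1**) and a lithifying state with a thin (30–50 µm)
CaCO₃ surface crust (**Type-2**). The transition is thought to be driven by
heterotrophic sulfate reducers: in Type-2 mats the SRM become abundant,
concentrate into a dense layer in the top ~130 µm, organise into clusters,
and co-locate with carbonate precipitates. Quantifying this from
fluorescence in-situ hybridization (FISH) confocal cross-sections requires
a chain of image-analysis and spatial-statistics steps, each of which is
hard to validate on natural material where no ground truth exists.

`stromspat` implements that chain as a tested, reusable pipeline, driven by
a synthetic-scene generator that plants known structure — so every stage
can be verified against exact ground truth:

* **Scene simulation** — ground-truthed multi-channel confocal scenes of
  Type-1 mats (sparse SRM placed by complete spatial randomness, ~21 % of
  cell area), Type-2 mats (Thomas-cluster SRM at ~88 % of cell area in the
  surface layer, beneath a near-continuous crust), and 1.0-µm microsphere
  calibration fields in a five-step dilution series (c, c/2, c/4, c/8, c/16).
* **Classification** — supervised minimum-distance pixel classification
  from representative training pixels; iterative two-class (2-means)
  foreground segmentation; morphological identification and subtraction of
  (possibly discontinuous) cyanobacterial filaments; probe/counterstain
  co-localization gating; object counting with a fragment "counting rule".
* **Microspatial statistics** — SRM share of cell area in a surface buffer
  zone (100 map pixels ≈ 133 µm deep); vertical depth profiles; cluster
  detection by dissolving overlapping 10-µm concentric regions (selected
  when > 5 cells); the pair correlation function g(r) on r = 0.1–6.44 µm
  with translation edge correction and CSR envelopes; per-threshold
  fractions of near-precipitate bacteria that are SRM (≤ 1.1, 2.2, 4.4 µm).
* **Calibration and statistics** — area-derived vs direct vs known
  microsphere counts with their three Pearson correlations; Welch t-test,
  one-way ANOVA with Bonferroni and Scheffé post-hoc decisions, and
  Pearson correlation with t-distributed p-values.

## The statistics at the core

The pair correlation function is estimated by ring counts with translation
edge correction in a bounded window W × H of area A:

    ĝ(r) = A / (n_a · n_b′) · Σ_{i≠j} 1[|d_ij − r| ≤ w/2] / (2π r w c_ij),
    c_ij = (W − |dx_ij|)(H − |dy_ij|) / (W · H)

with ring width w = 0.25 µm; ĝ ≈ 1 indicates spatial randomness, ĝ > 1
clustering, ĝ < 1 avoidance. The clustered alternative is the Thomas
process (parent intensity κ, offspring dispersion σ), whose closed form

    g(r) = 1 + exp(−r² / 4σ²) / (4π κ σ²)

serves as an independent oracle for the estimator. Cluster detection links
cells whose 10-µm concentric regions overlap (centroid distance < 10 µm)
and measures the dissolved disk-union area of each connected component.

## Worked example

```python
import stromspat as st
from stromspat.image import SurfaceLine

for name, spec in [("Type-1", st.type1_spec(seed=7)),
                   ("Type-2", st.type2_spec(seed=7))]:
    scene = st.build_scene(spec)           # ground truth: objects + masks
    image = st.render_scene(scene)         # noisy 3-channel confocal image
    surface = SurfaceLine(scene.surface_px, 1, scene.window.pixel_size_um)
    res = st.analyze_mat_image(image, srm_points_um=scene.srm_points(),
                               surface=surface, seed=7)
    print(f"{name}: SRM area fraction in buffer zone = {res.srm_area_percent:.1f}%")
    print(f"         selected clusters (>5 cells)   = "
          f"{int(res.clusters.table['selected'].sum())}")
    print(f"         g(r) exceeds CSR envelope      = {res.curve.exceeds_envelope()}")
```

prints

```
Type-1: SRM area fraction in buffer zone = 18.7%
         selected clusters (>5 cells)   = 0
         g(r) exceeds CSR envelope      = False
Type-2: SRM area fraction in buffer zone = 90.3%
         selected clusters (>5 cells)   = 31
         g(r) exceeds CSR envelope      = True
```

i.e. the pipeline recovers the planted abundances (targets 20.7 % and
88.0 % of cell area) from the rendered noisy images and correctly calls
the Type-2 scene clustered — selected clusters present and small-r ĝ above
the CSR envelope — while the Type-1 scene reads as spatially random. The
same analyses are available from the shell via the `stromspat` CLI
(`simulate`, `classify`, `analyze`, `calibrate`, `compare`, `report`).

## Limitations

Area-derived counts are relative abundance estimates, not absolute counts;
scenes are 2-D cross-sections with a Gaussian-blob optical model, not a
physical point-spread function; and the generator's clustering parameters
are calibrated to reproduce the qualitative Type-1/Type-2 contrast, not any
particular natural mat. See `docs/methods.md` for the full model
description and design rationale.
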
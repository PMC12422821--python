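# senesceope

Imaging cytometry of senescent cell subpopulations: stratify a senescent
culture into **G1- and G2-arrested subpopulations** from the integrated DAPI
intensity of each nucleus, and quantify subpopulation-resolved senescence
markers, IL-6 secretion and senolytic (ABT263/navitoclax) susceptibility.

Senescent cells are heterogeneous even within a single dish. One axis of that
heterogeneity is the cell-cycle phase at which the cell was arrested: a cell
irradiated in G2 carries ~4N DNA forever after, one arrested in G1 carries
~2N. Because integrated nuclear DAPI intensity is proportional to DNA
content, a high-content imaging experiment can gate every cell into G1 or G2
and ask whether the two subpopulations differ — in senescence marker
expression (γH2AX foci, p21, LaminB1, HMGB1, SA-β-Gal), in SASP output
(IL-6 per cell), and in how readily a senolytic kills them.

The package is aimed at people building or validating high-content screening
analyses of senescence: it contains the full analysis pipeline *and* a
synthetic microscope that renders plates with per-cell ground truth, so every
stage is testable without any real images.

## The model at the core

Per-cell integrated DNA content `x` is modelled on the log2 scale as a
two-component Gaussian mixture with a constrained mode spacing:

    log2 x  ~  (1 − w)·N(μ_G1, σ_G1²) + w·N(μ_G1 + δ, σ_G2²),   δ ∈ [0.8, 1.2]

The constraint anchors the fit to the 2× biology (G2 ≈ twice G1) while
absorbing staining nonlinearity. The model is fitted by EM (constrained
M-step, seeded restarts); the G1/G2 decision boundary is the log2 value where
the two weighted component densities are equal, with ties going to G1.
Because the gate is fitted per plate, it is invariant to global
staining-intensity rescaling between plates.

Downstream endpoints follow standard imaging-cytometry practice:

* fluorescence background = 20th percentile of each field's intensity
  histogram; integrated DNA = Σ(DAPI − bg) over the nuclear mask,
* γH2AX foci by white top-hat + robust (median + 5·MAD) threshold,
* SA-β-Gal as mean optical density −log10(I/I₀) over the expanded cell
  region of an absorbance-style brightfield channel,
* viability = well cell count / mean vehicle (0 µM) count of the same
  condition, with G1/G2 subpopulation counts normalized to their own vehicle
  means,
* IL-6 per 1000 cells = concentration × pooled volume / (pooled cells/1000),
* statistics on wells (never cells): one-way ANOVA + Tukey HSD, and
  Mann-Whitney U with Benjamini-Hochberg FDR across each contrast family.

## Worked example

Simulate a senescent G2-enriched plate (4 wells, ~2000 cells each), run the
pipeline, and inspect the gate:

```python
import warnings
from senesceope import (make_platemap, generate_plate, analyze_fields,
                        PipelineConfig, fit_dna_content_model)

pm = make_platemap(["IR-G2-E"], n_wells=4)
pairs = generate_plate(pm, seed=7, n_fields_per_well=2)
bundle = analyze_fields([f for f, _ in pairs], pm, PipelineConfig(seed=7))
print(bundle["phase_summary"])
print(fit_dna_content_model(bundle["cells"]["integrated_dna"], seed=7).summary())
```

Output:

```
well_id  n_cells    pct_g1    pct_g2
   W000     1019 39.646712 60.353288
   W001     1037 41.465767 58.534233
   W002      963 39.979232 60.020768
   W003     1014 39.053254 60.946746

DNA-content mixture (2-component, constrained spacing)
======================================================
n cells (positive DNA)            4041
excluded non-positive                0
mu_G1 (log2 a.u.)              17.6212
delta (log2 G2/G1 spacing)      0.9843
sigma_G1 / sigma_G2             0.1676 / 0.1728
G2 weight                       0.6001
boundary (log2 a.u.)           18.0948
log-likelihood                -1287.56
converged                         True
degenerate                       False
```

Reading it: the IR-G2-E preset encodes a population that is ~60% G2-arrested;
the fitted mixture finds the G1 mode at 2^17.62 ≈ 2.0×10⁵ intensity units,
a G2/G1 spacing of 0.98 log2 units (≈ the expected 2× DNA content), a G2
weight of 0.60, and the per-well gated percentages recover ~60% G2.

The same run is available from a shell:

```bash
senesceope simulate --config sim.yaml --out plate/
senesceope run --plate plate/ --platemap plate/platemap.yaml --out results/
```

## Layout

| module | contents |
|---|---|
| `senesceope.synth` | synthetic plate generator with per-cell ground truth |
| `senesceope.io` | TIFF+sidecar fields, plate maps, well assembly |
| `senesceope.segmentation` | Otsu + distance-transform-watershed nuclei masks |
| `senesceope.features` | background rule, intensities, foci, SA-β-Gal OD, morphology |
| `senesceope.cellcycle` | `DNAContentMixture` model / `DNAContentResults` gate |
| `senesceope.endpoints` | EdU calls, marker summaries, viability, IL-6 |
| `senesceope.stats` | ANOVA+Tukey, Mann-Whitney+BH on well-level data |
| `senesceope.pipeline` | orchestration, manifests, `senesceope` CLI |
| `senesceope.experiments` | desk-scale parameter-recovery studies |

See `docs/methods.md` for the full model and generator documentation.
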
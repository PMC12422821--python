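# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `senesceope`.

## 1. Biological setting

Ionizing radiation arrests cultured primary cells (here: endothelial-like and
fibroblast-like populations) in an essentially irreversible senescent state.
The cell-cycle phase *at the moment of irradiation* is frozen into the
senescent cell as its DNA content: G1-arrested cells carry ~2N, G2-arrested
cells ~4N. Culture protocols can enrich a population in either phase before
irradiation — serum starvation pushes cells toward G1, precisely timed
seeding into exponential growth raises the G2 fraction. The package analyses
such experiments: DAPI imaging yields per-cell integrated DNA content, a
two-mode model gates each cell G1/G2, and all downstream endpoints (marker
levels, viability under the senolytic ABT263, IL-6 secretion) are resolved by
subpopulation.

## 2. DNA-content gate

**Model.** Per-cell integrated DNA `x > 0` on the log2 scale:

    log2 x ~ (1−w)·N(μ, σ₁²) + w·N(μ+δ, σ₂²),  δ constrained to [0.8, 1.2].

The spacing constraint encodes that the G2 mode sits at ~2× the G1 mode
(δ = 1 exactly for a perfectly linear stain) while leaving room for staining
nonlinearity. Fitting is by EM:

* **Initialization.** μ is anchored at the dominant histogram mode (64 bins),
  δ = 1, σ₁ = σ₂ = std/2, w from the mass above the midpoint. Because in a
  G2-enriched population the dominant mode *is* the G2 mode, the restart
  schedule tries both readings (dominant mode = G1 and dominant mode = G2);
  additional restarts jitter μ (seeded). The best final log-likelihood wins.
* **M-step.** Given responsibilities, (μ, δ) solve the weighted least-squares
  normal equations with δ projected onto [0.8, 1.2] (and μ re-solved at the
  bound — the exact constrained maximizer); then σ₁, σ₂, w update in closed
  form. This is an ECM scheme, so the log-likelihood is non-decreasing
  (property-tested).
* **Boundary.** The G1/G2 decision threshold is the log2 value where the two
  weighted component densities are equal, found by root-bracketing strictly
  between the modes; if no crossing exists there (extreme weights), the
  midpoint μ + δ/2 is used. A value exactly at the boundary is called G1.
* **Diagnostics.** A fit with w outside [0.01, 0.99] or a collapsed σ is
  flagged degenerate (warning, recorded in the run manifest). Fewer than 50
  positive cells is an error. Non-positive intensities are excluded and
  tallied; cells outside [2^(μ−3σ₁), 2^(μ+δ+3σ₂)] are flagged
  debris/multinucleated and dropped from phase fractions.

The gate is fitted **per plate**, pooling all wells of one cell type
(robust to between-plate staining drift); per-well fitting is a config
switch. The output is two-class by design: irradiation-arrested populations
are EdU-negative, and the mid-S cells present in proliferating controls are
knowingly absorbed into the nearer class (see §6 Limitations).

## 3. Image processing

* **Background**: the 20th percentile of each field's intensity histogram,
  per channel (linear-interpolation percentile convention). Estimating per
  field makes the rule robust to field-level illumination differences.
* **Segmentation**: background subtraction → Gaussian smoothing
  (σ = 0.6 px default) → global Otsu threshold on the log-compressed image →
  hole filling → distance-transform watershed (peak separation 10 px) →
  area filter [80, 8000] px² and border discard. Otsu is applied on
  log(1+I) because nuclear brightness spans ~an order of magnitude (2N vs 4N
  plus staining noise); a linear-scale threshold erodes dim nuclei far more
  than bright ones, which would bias the very quantity being gated.
  Border-touching nuclei are discarded because their truncated integrated
  DNA would corrupt the gate. The smoothing default is small because the
  modelled optics (20×, 1.3 µm/px) already band-limit the image; heavier
  smoothing inflates every mask by several pixels. All thresholds are
  exposed in `SegmentationParams`.
* **Cell region**: each nucleus is expanded by 6 px (≈8 µm) with ties broken
  by Euclidean distance — a proxy for cytoplasmic segmentation used only by
  the SA-β-Gal readout, which is lysosomal/cytoplasmic. All five ICC markers
  are nuclear and use the nuclear mask.
* **Morphology**: area (µm²), Crofton perimeter, shape factor 4πA/P²
  (defined as circularity; 1 for a disk), aspect ratio of the best-fit
  ellipse.
* **Foci**: white top-hat (disk r = 3 px), per-nucleus threshold at
  median + 5·MAD of the top-hat signal, connected components with area in
  [2, 50] px. On noise-only nuclei the false-positive rate is < 0.1
  foci/nucleus (tested).
* **SA-β-Gal**: I₀ = median brightfield intensity over background pixels;
  per-cell OD = mean of −log10(I/I₀) over the cell region, clipped at 0.
* **EdU positivity**: Otsu on log(1+EdU mean) pooled over the plate, with a
  bimodality floor — the split must separate class means by ≥1.5 log units
  (≈4.5-fold), otherwise a fixed threshold is used with a warning. EdU+
  nuclei are orders of magnitude brighter than unlabeled nuclei, so a
  genuine split always clears the floor.

## 4. Well-level endpoints and statistics

Viability = well cell count / mean vehicle-well (0 µM) count of the same
condition. Subpopulation viability divides G1 (resp. G2) counts by the mean
vehicle G1 (resp. G2) counts, so both per-phase dose-response curves start
at 1 — the only normalization under which per-phase curves are directly
comparable. IL-6 per 1000 cells = concentration (pg/mL) × pooled volume
(mL) / (pooled cells / 1000), matching ELISA on conditioned medium pooled
from ≥3 wells with imaging-derived counts.

Statistical units are wells, never cells. The battery is one-way ANOVA with
Tukey HSD post-hoc (marker/secretion group contrasts) and two-sided
Mann-Whitney U — exact for group sizes ≤ 8 without ties, tie-corrected
normal otherwise — with Benjamini-Hochberg correction applied across the
contrasts supplied in one call (the per-figure-panel analogue: all
dose × group contrasts of one experiment). Both tests hold their nominal 5%
level on null data (Monte-Carlo tested at 1000 reps).

## 5. Synthetic-data generator

The generator emulates the acquisition geometry the analysis assumes:
16-bit 1024×1024 fields at 1.3 µm/px, DAPI plus up to four nuclear marker
channels plus an absorbance-style brightfield channel.

* **Nuclei** are anisotropic ellipses (axis ratio U(1, 1.6), lognormal area)
  rendered as flat-top "super-Gaussian" plateaus exp(−½(d/0.85)⁶) truncated
  at the ellipse boundary. The flat top with a moderately sharp rim is what
  real DAPI nuclei look like at this magnification, and it makes the
  footprint recoverable by thresholding. Senescent presets use ~1.75× the
  control nuclear area (direction: senescent nuclei are enlarged; magnitude
  is a free default). Placement is rejection sampling with a minimum
  centroid spacing of 2.6× the mean radius; cells stay clear of the border.
* **DNA content**: G1 cells lognormal (mean 2×10⁵ a.u., CV 0.12), G2 cells
  2× a G1 draw, mid-S cells a G1 draw × U(1, 2). The CV is a free default
  (not reported for the modelled experiments); 0.12 gives the clean but
  non-trivially overlapping bimodal histograms characteristic of imaging
  cytometry.
* **Condition presets** encode the enrichment protocol's outcomes as gated
  G2 percentages: CTL-G1-E 20%, CTL-G2-E 40%, IR-G1-E 30%, IR-G2-E 60%.
  Proliferating control presets include a 10% mid-S fraction; since the
  two-class gate absorbs an S cell into G2 with probability 2−√2 ≈ 0.586
  (mass of U(1,2) above the geometric-mean boundary √2), the latent true-G2
  probability is solved as p_G2 = g2_fraction − s_fraction·(2−√2) so that
  the *measured* G2 call rate matches the preset. Irradiated presets have no
  S cells (they are EdU-negative).
* **Markers**: per-cell mean levels are lognormal around phase-dependent
  means; senescent presets carry high γH2AX/p21 and reduced LaminB1/HMGB1,
  with G2-arrested cells more extreme in the senescence direction. γH2AX
  foci are Poisson counts (λ = 6 G1 / 10 G2 in senescent presets, <1 in
  controls) rendered as σ = 1.5 px Gaussian puncta with ≥3σ separation
  (best effort). EdU level is driven by a per-cell positivity flag with
  phase-dependent probability (proliferating controls only).
* **Noise and background**: Poisson photon shot noise plus Gaussian read
  noise (σ = 2) on every channel; fluorescence background is a 100-count
  pedestal plus a 10-count linear gradient in a random direction, so the
  20th-percentile estimator is meaningfully exercised. The gradient
  amplitude keeps the estimator's integrated-DNA bias below 1% (tested).
* **SA-β-Gal brightfield**: transmitted light I = I₀·10^(−OD) with I₀ = 80%
  of the dynamic range; the per-cell OD (lognormal around the preset mean)
  is painted over the cell footprint expanded 2 px beyond the measured
  region, and overlapping deposits take the per-pixel maximum rather than
  summing. Preset ODs: senescent endothelial-like 0.25, fibroblast-like
  0.05 (a 5-fold cell-type contrast), controls 0.02.
* **Senolysis**: each alive cell dies independently with per-phase
  exponential survival s(d) = exp(−k·d), defaults k_G1 = 0.25/µM,
  k_G2 = 1.10/µM (G2-arrested senescent cells are more ABT263-susceptible;
  chosen so the subpopulation difference is detectable at 0.11, 0.33 and
  1.00 µM over 30 wells). Dead cells are absent from rendered images but
  retained in the truth table — an endpoint-fixation assay has no corpses.
* **IL-6**: per-condition secretion rates (pg/1000 cells: CTL 2,
  IR-G1-E 10, IR-G2-E 25) with 15% lognormal assay noise; only the ordering
  IR-G2-E > IR-G1-E > CTL is treated as meaningful.
* **Determinism**: one master seed; per-well and per-field generators derive
  from `SeedSequence(master, spawn_key=(well, field))`, so plates are
  byte-identical across runs and independent of iteration order.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: confluent monolayers with heavy nuclear
overlap, out-of-focus fields, photorealistic chromatin texture,
illumination artifacts beyond a linear gradient, debris and multinucleated
cells, corpse retention after senolysis, and any vendor file format
(interchange is multi-page TIFF + JSON sidecar; 5×5 field grids are
concatenated without registration, as tiles are recorded without overlap).

## 6. Problem sizes and numerical choices

* Recovery studies run at desk scale: 16 wells × 4 fields × ~500 cells per
  enrichment plate (~32k cells/plate), 6 wells × 2 fields per SA-β-Gal
  population, and 30 wells × 2000 cells per dose for the (truth-level)
  senolysis study. These sizes put Monte-Carlo error well inside the
  recovery tolerances while keeping a full run a few minutes on one CPU.
* The senolysis study is computed on generator truth tables (counts through
  gating and vehicle normalization, no pixel rendering): its quantities are
  count ratios, and rendering would only add runtime; imaging fidelity is
  covered by the enrichment and SA-β-Gal studies and the segmentation
  property tests.
* EM: 3 restarts, tolerance 1e-9 on the log-likelihood, ≤300 iterations;
  σ floored at 1e-4 to avoid singular components.
* Bootstrap fold-change CIs: 2000 well-level resamples, percentile method,
  seeded.

## 7. Known limitations

* Mid-S cells in proliferating controls are forced into G1 or G2; with the
  default 10% S fraction this is compensated in expectation (§5) but
  individual S cells are unavoidably miscalled. Phase-call accuracy is
  therefore quoted with S cells excluded.
* The per-phase exponential kill model makes the whole-population viability
  difference between differently-enriched populations significant at every
  dose; real dose-response data showed the whole-population contrast only at
  the two higher doses. The generator reproduces the subpopulation effect
  (the analysis target), not that whole-population nuance.
* Between-condition SA-β-Gal contrasts assume comparable cell-region
  geometry; strongly different cell shapes would mix geometry into the OD
  ratio.
* The segmentation is designed for non-confluent cultures; it has no
  special handling for clumps beyond the watershed split.
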
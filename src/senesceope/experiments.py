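"""Desk-scale reproduction experiments on the synthetic generator.

Each function regenerates its inputs from a seed, runs the relevant slice of
the pipeline, and returns the recovered quantities.  These are the package's
headline parameter-recovery studies:

* G1/G2 enrichment — four enrichment presets (CTL-G1-E, CTL-G2-E, IR-G1-E,
  IR-G2-E) carry gated-G2 targets of ~20/40/30/60%; full imaging plates are
  segmented and gated and the mean per-well G2 percentage is recovered.
* SA-β-Gal cell-type contrast — senescent endothelial-like vs
  fibroblast-like populations differ ~5-fold in per-cell optical density.
* Subpopulation senolysis — per-phase exponential kill makes G2-arrested
  cells more ABT263-susceptible than G1-arrested ones at 0.11/0.33/1.00 µM;
  recovered subpopulation viabilities are compared by Mann-Whitney with
  Benjamini-Hochberg correction, and checked against the closed form
  viability_G2/viability_G1 = exp(-(k_G2-k_G1)·dose).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .cellcycle import fit_dna_content_model, phase_fractions
from .config import GeneratorConfig, get_preset
from .endpoints import compute_viability
from .features import extract_features, sabgal_od
from .io import PlateMap
from .pipeline import PipelineConfig, extract_cells, gate_cells
from .segmentation import expand_to_cell_region, segment_nuclei
from .stats import mannwhitney_fdr
from .synth import (apply_senolysis, generate_plate, make_platemap,
                    sample_truth, well_seed_sequence)

#: expected mean per-well gated G2 percentage per enrichment preset
G2_TARGETS = {"CTL-G1-E": 20.0, "CTL-G2-E": 40.0, "IR-G1-E": 30.0, "IR-G2-E": 60.0}

SENOLYSIS_DOSES = (0.11, 0.33, 1.00)


def _imaging_only_config(name: str, channels=()) -> GeneratorConfig:
    """Preset stripped to the channels an experiment actually consumes."""
    return get_preset(name).replace(
        channels=tuple(channels),
        include_brightfield="brightfield_sabgal" in channels,
    )


def g2_recovery_experiment(
    preset: str,
    seed: int,
    n_wells: int = 16,
    n_fields_per_well: int = 4,
) -> dict:
    """Recover the mean per-well G2 percentage of one enrichment preset.

    Renders a DAPI-only plate (~2000 cells/well), segments, extracts
    integrated DNA, fits the pooled mixture and gates every cell.
    """
    pm = make_platemap([preset], n_wells=n_wells)
    config = _imaging_only_config(preset)
    pairs = generate_plate(pm, {preset: config}, seed=seed,
                           n_fields_per_well=n_fields_per_well)
    cells = extract_cells((f for f, _ in pairs), PipelineConfig(seed=seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells, qc = gate_cells(cells, PipelineConfig(seed=seed))
        summary = phase_fractions(cells)
    return {
        "preset": preset,
        "mean_pct_g2": float(summary["pct_g2"].mean()),
        "phase_summary": summary,
        "n_cells": int(qc["n_cells"]),
        "model": qc["models"]["plate"],
    }


def sabgal_ratio_experiment(
    seed: int,
    n_wells: int = 6,
    n_fields_per_well: int = 2,
    presets: tuple[str, str] = ("IR", "IR-FIBRO"),
) -> dict:
    """Ratio of mean per-cell SA-β-Gal OD between two senescent cell types.

    Renders DAPI + brightfield, segments nuclei, expands to cell regions and
    measures per-cell optical density for each population.
    """
    means = {}
    counts = {}
    for pi, preset in enumerate(presets):
        pm = make_platemap([preset], n_wells=n_wells)
        config = _imaging_only_config(preset, channels=("brightfield_sabgal",))
        pairs = generate_plate(pm, {preset: config}, seed=seed + pi,
                               n_fields_per_well=n_fields_per_well)
        ods = []
        for field, _ in pairs:
            nuclei = segment_nuclei(field.channel("dna"))
            regions = expand_to_cell_region(nuclei, config.cell_expand_px)
            ods.extend(sabgal_od(field, regions).values())
        means[preset] = float(np.mean(ods))
        counts[preset] = len(ods)
    a, b = presets
    return {
        "od_means": means,
        "n_cells": counts,
        "ratio": means[a] / means[b],
    }


def senolysis_experiment(
    seed: int,
    n_wells: int = 30,
    cells_per_well: int = 2000,
    doses: tuple[float, ...] = SENOLYSIS_DOSES,
    populations: tuple[str, ...] = ("IR-G2-E", "IR-G1-E"),
) -> dict:
    """Dose-resolved G1/G2 subpopulation viability under the senolytic model.

    Truth-level study (counts, not pixels): per population and dose, draw
    ``n_wells`` wells, apply per-phase exponential kill, gate the surviving
    cells with the pooled DNA-content mixture and compute vehicle-normalized
    subpopulation viability; all G2-vs-G1 contrasts form one BH family.
    """
    all_doses = (0.0,) + tuple(d for d in doses if d > 0)
    frames = []
    for pi, pop in enumerate(populations):
        config = get_preset(pop)
        wells = {}
        rows = []
        widx = 0
        for dose in all_doses:
            for _ in range(n_wells):
                well_id = f"{pop}_d{dose:.2f}_{widx:03d}"
                wells[well_id] = {"condition": pop, "dose_uM": dose}
                rng = np.random.default_rng(
                    well_seed_sequence(seed + 1000 * pi, widx))
                truth = sample_truth(config, cells_per_well, rng,
                                     well_id=well_id, place=False)
                truth = apply_senolysis(truth, dose, config.dose_response, rng)
                rows.append(truth[truth["alive"]])
                widx += 1
        pm = PlateMap.from_dict(wells)
        alive = pd.concat(rows, ignore_index=True)

        model = fit_dna_content_model(alive["true_integrated_dna"], seed=seed)
        alive = alive.assign(
            phase=model.classify(alive["true_integrated_dna"].to_numpy()).to_numpy())
        counts = (
            alive.groupby("well_id")
            .agg(n_cells=("cell_id", "size"),
                 n_g1=("phase", lambda p: int((p == "G1").sum())),
                 n_g2=("phase", lambda p: int((p == "G2").sum())))
            .reset_index()
        )
        v = compute_viability(counts, pm)
        frames.append(v)
    viability = pd.concat(frames, ignore_index=True)

    pairs = []
    for pop in populations:
        for dose in doses:
            grp = viability[(viability["condition"] == pop)
                            & (viability["dose_uM"] == dose)]
            pairs.append((f"{pop} @ {dose:.2f} uM",
                          grp["viability_g2"].to_numpy(),
                          grp["viability_g1"].to_numpy()))
    comparisons = mannwhitney_fdr(pairs)

    k = get_preset(populations[0]).dose_response
    ratio_rows = []
    for pop in populations:
        for dose in doses:
            grp = viability[(viability["condition"] == pop)
                            & (viability["dose_uM"] == dose)]
            ratio_rows.append({
                "condition": pop, "dose_uM": dose,
                "viability_g1": grp["viability_g1"].mean(),
                "viability_g2": grp["viability_g2"].mean(),
                "ratio_g2_g1": grp["viability_g2"].mean() / grp["viability_g1"].mean(),
                "ratio_expected": math.exp(-(k.k_g2 - k.k_g1) * dose),
            })
    return {
        "viability": viability,
        "comparisons": comparisons,
        "ratios": pd.DataFrame(ratio_rows),
    }
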
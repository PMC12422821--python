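"""End-to-end orchestration: segment -> extract -> gate -> endpoints -> stats.

`analyze_fields` is the in-memory core; `run_pipeline` wraps it with disk IO
and writes per-cell/per-well tables plus a run manifest (config hash, seed,
versions, QC tallies) so a run is reproducible from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellcycle import DNAContentMixture, phase_fractions
from .endpoints import (EdUParams, call_edu_positive, compute_viability,
                        summarize_markers_by_phase)
from .features import MARKER_FEATURES, FeatureParams, extract_features
from .io import FieldImage, PlateMap, iter_plate_fields
from .segmentation import SegmentationParams, expand_to_cell_region, segment_nuclei
from .stats import anova_tukey, mannwhitney_fdr, results_to_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    edu: EdUParams = field(default_factory=EdUParams)
    cell_expand_px: int = 6
    fit_per_well: bool = False
    em_restarts: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            segmentation=SegmentationParams(**raw.get("segmentation", {})),
            features=FeatureParams(**raw.get("features", {})),
            edu=EdUParams(**raw.get("endpoints", {}).get("edu", {})
                          if "endpoints" in raw else raw.get("edu", {})),
            cell_expand_px=int(raw.get("cell_expand_px", 6)),
            fit_per_well=bool(raw.get("cellcycle", {}).get("fit_per_well", False)),
            em_restarts=int(raw.get("cellcycle", {}).get("em_restarts", 3)),
            seed=int(raw.get("seed", 0)),
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def extract_cells(fields: Iterable[FieldImage],
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Segment every field and extract per-cell features into one table."""
    config = config or PipelineConfig()
    frames = []
    missing_roles: set[str] = set()
    last_well = None
    for f in fields:
        if f.well_id != last_well:
            logger.info("processing well %s", f.well_id)
            last_well = f.well_id
        nuclei = segment_nuclei(f.channel("dna"), config.segmentation, f.field_id)
        regions = expand_to_cell_region(nuclei, config.cell_expand_px)
        cells = extract_features(f, nuclei, regions, config.features)
        missing_roles |= {r for r in MARKER_FEATURES if not f.has_channel(r)}
        if not cells.empty:
            frames.append(cells)
    if missing_roles:
        logger.info("channels absent on this plate, features skipped: %s",
                    ", ".join(sorted(missing_roles)))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def gate_cells(cells: pd.DataFrame, config: PipelineConfig | None = None
               ) -> tuple[pd.DataFrame, dict]:
    """Fit the DNA-content mixture and assign G1/G2 phases (NA for debris).

    Fits once on the pooled plate by default, or per well with
    ``config.fit_per_well``.
    """
    config = config or PipelineConfig()
    cells = cells.copy()
    qc = {"n_cells": len(cells), "n_debris": 0, "n_nonpositive": 0,
          "degenerate_fits": 0, "models": {}}

    def _fit_and_assign(df: pd.DataFrame, key: str) -> pd.Series:
        model = DNAContentMixture(df["integrated_dna"])
        results = model.fit(n_restarts=config.em_restarts, seed=config.seed)
        phase = results.classify(df["integrated_dna"].to_numpy())
        debris = results.debris_mask(df["integrated_dna"].to_numpy())
        phase[debris] = pd.NA
        qc["n_debris"] += int(debris.sum())
        qc["n_nonpositive"] += results.qc.get("n_excluded_nonpositive", 0)
        qc["degenerate_fits"] += int(results.degenerate)
        qc["models"][key] = {
            "mu_g1": results.mu_g1, "delta": results.delta,
            "sigma_g1": results.sigma_g1, "sigma_g2": results.sigma_g2,
            "w_g2": results.w_g2, "boundary": results.boundary,
            "loglike": results.loglike, "n": results.n,
        }
        return phase.set_axis(df.index)

    if config.fit_per_well:
        parts = [_fit_and_assign(grp, well) for well, grp in
                 cells.groupby("well_id", sort=True)]
        cells["phase"] = pd.concat(parts).reindex(cells.index)
    else:
        cells["phase"] = _fit_and_assign(cells, "plate")
    return cells, qc


def well_counts(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-well total/G1/G2 cell counts for viability endpoints."""
    rows = []
    for well_id, grp in cells.groupby("well_id", sort=True):
        rows.append({
            "well_id": well_id,
            "n_cells": len(grp),
            "n_g1": int((grp["phase"] == "G1").sum()),
            "n_g2": int((grp["phase"] == "G2").sum()),
        })
    return pd.DataFrame(rows)


def analyze_fields(fields: Iterable[FieldImage], plate_map: PlateMap,
                   config: PipelineConfig | None = None) -> dict:
    """Run the full analysis on in-memory fields; returns a bundle of tables."""
    config = config or PipelineConfig()

    try:
        cells = extract_cells(fields, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("segmentation/features", str(exc)) from exc
    if cells.empty:
        raise PipelineError("segmentation/features", "no cells found on the plate")
    cells["condition"] = cells["well_id"].map(lambda w: plate_map[w].condition)
    cells["dose_uM"] = cells["well_id"].map(lambda w: plate_map[w].dose_uM)

    try:
        cells, qc = gate_cells(cells, config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cellcycle", str(exc)) from exc

    phases = phase_fractions(cells)
    counts = well_counts(cells)

    edu_wells = None
    if "edu_mean" in cells.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, edu_wells = call_edu_positive(cells, config.edu)

    markers = summarize_markers_by_phase(cells, plate_map)

    viability = None
    has_vehicle = all(
        any(plate_map[w].dose_uM == 0 and plate_map[w].condition == cond
            for w in plate_map.well_ids())
        for cond in plate_map.conditions())
    if has_vehicle:
        try:
            viability = compute_viability(counts, plate_map)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("endpoints", str(exc)) from exc

    comparisons = _default_comparisons(phases, viability, plate_map)
    return {
        "cells": cells, "phase_summary": phases, "well_counts": counts,
        "edu_wells": edu_wells, "marker_summary": markers,
        "viability": viability, "comparisons": comparisons, "qc": qc,
    }


def _default_comparisons(phases: pd.DataFrame, viability: pd.DataFrame | None,
                         plate_map: PlateMap) -> pd.DataFrame | None:
    """Standard battery: pct_g2 across conditions; G1 vs G2 viability per dose."""
    results = []
    merged = phases.copy()
    merged["condition"] = merged["well_id"].map(lambda w: plate_map[w].condition)
    groups = {c: g["pct_g2"].to_numpy() for c, g in merged.groupby("condition")
              if len(g) >= 2}
    if len(groups) >= 2:
        try:
            results.extend(anova_tukey(groups))
        except ValueError as exc:
            logger.warning("skipping pct_g2 ANOVA: %s", exc)

    if viability is not None:
        pairs = []
        for (cond, dose), grp in viability.groupby(["condition", "dose_uM"]):
            if dose == 0 or len(grp) < 3:
                continue
            pairs.append((f"{cond} {dose:g} uM: viability G2 vs G1",
                          grp["viability_g2"].dropna().to_numpy(),
                          grp["viability_g1"].dropna().to_numpy()))
        if pairs:
            try:
                results.extend(mannwhitney_fdr(pairs))
            except ValueError as exc:
                logger.warning("skipping viability Mann-Whitney: %s", exc)
    return results_to_frame(results) if results else None


def run_pipeline(plate_dir, plate_map_path, config=None, out_dir=None) -> dict:
    """Disk-to-disk pipeline run with manifest; returns the result bundle."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    config = config or PipelineConfig()
    plate_map = (plate_map_path if isinstance(plate_map_path, PlateMap)
                 else PlateMap.from_yaml(plate_map_path))

    try:
        fields = list(iter_plate_fields(plate_dir))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("io", str(exc)) from exc
    if not fields:
        raise PipelineError("io", f"no TIFF fields found under {plate_dir}")

    bundle = analyze_fields(fields, plate_map, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["cells"].to_csv(out / "cells.csv", index=False)
        bundle["phase_summary"].to_csv(out / "phase_summary.csv", index=False)
        bundle["well_counts"].to_csv(out / "well_counts.csv", index=False)
        bundle["marker_summary"].to_csv(out / "marker_summary.csv", index=False)
        if bundle["edu_wells"] is not None:
            bundle["edu_wells"].to_csv(out / "edu_wells.csv", index=False)
        if bundle["viability"] is not None:
            bundle["viability"].to_csv(out / "viability.csv", index=False)
        if bundle["comparisons"] is not None:
            bundle["comparisons"].to_csv(out / "comparisons.csv", index=False)
        manifest = {
            "package_version": __version__,
            "config_digest": config.digest(),
            "config": asdict(config),
            "seed": config.seed,
            "versions": _library_versions(),
            "n_fields": len(fields),
            "qc": {k: v for k, v in bundle["qc"].items() if k != "models"},
            "models": bundle["qc"]["models"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return bundle


def _library_versions() -> dict[str, str]:
    import scipy
    import skimage

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-image": skimage.__version__}
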
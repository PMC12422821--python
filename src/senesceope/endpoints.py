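"""Well-level endpoints: EdU positivity, marker summaries by phase, viability, IL-6.

Viability follows the vehicle-normalization used for senolytic dose-response:
each well's cell count is divided by the mean count of the 0-dose (vehicle)
wells of the same condition.  Subpopulation viability normalizes the G1 and G2
counts to their *own* vehicle means, so both per-phase curves start at 1.

IL-6 is reported per 1000 cells: concentration (pg/mL) x pooled volume (mL) /
(pooled cell count / 1000), mirroring ELISA on conditioned medium pooled from
several wells with imaging-derived cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .io import PlateMap

MARKER_SUMMARY_COLS = (
    "gH2AX_mean", "p21_mean", "laminB1_mean", "hmgb1_mean", "edu_mean",
    "foci_count", "sabgal_od", "nuclear_area_um2", "shape_factor",
)


@dataclass(frozen=True)
class EdUParams:
    fixed_threshold: float = 50.0       # a.u. background-corrected nuclear mean
    # bimodality floor: the Otsu split must separate class means by this many
    # log(1+x) units (~4.5-fold in intensity); EdU+ nuclei are orders of
    # magnitude brighter than unlabeled ones, so anything less is unimodal
    min_separation: float = 1.5


def call_edu_positive(records: pd.DataFrame, params: EdUParams | None = None
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """Call EdU-positive cells and summarize per-well percent positive.

    The threshold is chosen by Otsu on log(1 + background-corrected EdU mean)
    pooled over the plate; if the distribution is effectively unimodal (the
    Otsu split separates the class means by less than ``min_separation`` log
    units) the fixed threshold is used instead, with a warning.
    """
    params = params or EdUParams()
    values = records["edu_mean"].to_numpy(float)
    logv = np.log1p(np.clip(values, 0.0, None))
    threshold = np.log1p(params.fixed_threshold)
    use_otsu = False
    finite = logv[np.isfinite(logv)]
    if finite.size >= 2 and np.ptp(finite) > 0:
        t = threshold_otsu(finite)
        lo, hi = finite[finite <= t], finite[finite > t]
        if lo.size and hi.size and hi.mean() - lo.mean() >= params.min_separation:
            threshold = t
            use_otsu = True
    if not use_otsu:
        warnings.warn(
            "EdU distribution not clearly bimodal; using fixed threshold",
            stacklevel=2)

    positive = pd.Series(logv > threshold, index=records.index, name="edu_positive")
    per_well = (
        pd.DataFrame({"well_id": records["well_id"], "edu_positive": positive})
        .groupby("well_id", sort=True)["edu_positive"]
        .agg(pct_edu_positive=lambda s: 100.0 * s.mean(), n_cells="size")
        .reset_index()
    )
    return positive, per_well


def summarize_markers_by_phase(records: pd.DataFrame,
                               plate_map: PlateMap | None = None) -> pd.DataFrame:
    """Well x phase mean marker levels (plus whole-well rows, phase='all').

    Statistical units downstream are wells, never cells; this is the bridge
    from per-cell records to the well-level tables the stats battery consumes.
    """
    cols = [c for c in MARKER_SUMMARY_COLS if c in records.columns]
    frames = []
    usable = records.dropna(subset=["phase"]) if "phase" in records else records
    for scope, df in (("all", records), ("G1", usable[usable["phase"] == "G1"]),
                      ("G2", usable[usable["phase"] == "G2"])):
        if df.empty:
            continue
        g = df.groupby("well_id", sort=True)[cols].mean().reset_index()
        g.insert(1, "phase", scope)
        g["n_cells"] = df.groupby("well_id", sort=True).size().to_numpy()
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    if plate_map is not None:
        out.insert(1, "condition",
                   out["well_id"].map(lambda w: plate_map[w].condition))
    return out


def compute_viability(counts: pd.DataFrame, plate_map: PlateMap) -> pd.DataFrame:
    """Vehicle-normalized viability per well, total and by G1/G2 subpopulation.

    ``counts`` needs columns well_id, n_cells, n_g1, n_g2.  For each condition
    the vehicle (dose 0) well means define the denominators; conditions
    without a vehicle well raise.
    """
    df = counts.copy()
    df["condition"] = df["well_id"].map(lambda w: plate_map[w].condition)
    df["dose_uM"] = df["well_id"].map(lambda w: plate_map[w].dose_uM)

    out = []
    for cond, grp in df.groupby("condition", sort=True):
        vehicle = grp[grp["dose_uM"] == 0.0]
        if vehicle.empty:
            raise ValueError(f"condition {cond!r} has no vehicle (dose 0) wells")
        ref_total = vehicle["n_cells"].mean()
        ref_g1 = vehicle["n_g1"].mean()
        ref_g2 = vehicle["n_g2"].mean()
        g = grp.copy()
        g["viability_total"] = g["n_cells"] / ref_total
        g["viability_g1"] = g["n_g1"] / ref_g1 if ref_g1 > 0 else np.nan
        g["viability_g2"] = g["n_g2"] / ref_g2 if ref_g2 > 0 else np.nan
        out.append(g)
    return pd.concat(out, ignore_index=True)[
        ["well_id", "condition", "dose_uM", "n_cells", "n_g1", "n_g2",
         "viability_total", "viability_g1", "viability_g2"]
    ]


def normalize_il6(secretion: pd.DataFrame) -> pd.DataFrame:
    """Normalize ELISA IL-6 concentrations to imaging-derived cell counts.

    il6_per_1000_cells = il6_pg_per_ml x pooled_volume_ml / (cells / 1000).
    """
    df = secretion.copy()
    if (df["pooled_cell_count"] <= 0).any():
        raise ValueError("pooled_cell_count must be > 0")
    if (df["pooled_volume_ml"] <= 0).any():
        raise ValueError("pooled_volume_ml must be > 0")
    if (df["il6_pg_per_ml"] < 0).any():
        raise ValueError("il6_pg_per_ml must be >= 0")
    df["il6_per_1000_cells"] = (
        df["il6_pg_per_ml"] * df["pooled_volume_ml"]
        / (df["pooled_cell_count"] / 1000.0)
    )
    return df
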
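"""Endpoint tests: EdU calling, phase-resolved markers, viability, IL-6."""

import math

import numpy as np
import pandas as pd
import pytest

from senesceope import (call_edu_positive, summarize_markers_by_phase,
                        compute_viability, normalize_il6, PlateMap,
                        get_preset, sample_truth, simulate_secretion)
from senesceope.config import DoseResponse, MarkerParams
from senesceope.endpoints import EdUParams
from senesceope.synth import apply_senolysis


def _records_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Measurement-level records straight from latent truth (no imaging noise)."""
    rec = pd.DataFrame({
        "well_id": truth["well_id"],
        "edu_mean": truth["true_edu_mean"],
        "gH2AX_mean": truth["true_gH2AX_mean"],
        "p21_mean": truth["true_p21_mean"],
        "phase": truth["true_phase"].where(truth["true_phase"] != "S", pd.NA),
    })
    return rec


class TestEdU:
    def test_bimodal_population_recovers_positive_fraction(self):
        config = get_preset("CTL")
        truth = pd.concat([
            sample_truth(config, 800, np.random.default_rng(s),
                         well_id=f"W{s}", place=False)
            for s in range(4)], ignore_index=True)
        positive, per_well = call_edu_positive(_records_from_truth(truth))
        true_pct = 100.0 * truth["edu_positive"].mean()
        assert abs(per_well["pct_edu_positive"].mean() - true_pct) < 3.0

    def test_arrested_population_mostly_negative(self):
        config = get_preset("IR-G2-E")
        truth = sample_truth(config, 2000, np.random.default_rng(1), place=False)
        with pytest.warns(UserWarning, match="bimodal"):
            positive, per_well = call_edu_positive(_records_from_truth(truth))
        assert per_well["pct_edu_positive"].mean() < 2.0

    def test_all_zero_channel_falls_back_to_fixed_threshold(self):
        rec = pd.DataFrame({"well_id": ["A"] * 100, "edu_mean": 0.0})
        with pytest.warns(UserWarning, match="bimodal"):
            positive, per_well = call_edu_positive(rec)
        assert per_well["pct_edu_positive"].iloc[0] == 0.0


class TestMarkerSummary:
    def test_twofold_g2_marker_recovered(self):
        config = get_preset("IR").replace(marker_params={
            "gH2AX": MarkerParams(mean_g1=300, mean_g2=600, cv=0.2),
            "p21": MarkerParams(mean_g1=400, mean_g2=800, cv=0.2),
        })
        truth = pd.concat([
            sample_truth(config, 600, np.random.default_rng(s),
                         well_id=f"W{s}", place=False)
            for s in range(4)], ignore_index=True)
        out = summarize_markers_by_phase(_records_from_truth(truth))
        by = out.groupby("phase")[["gH2AX_mean", "p21_mean"]].mean()
        assert by.loc["G2", "gH2AX_mean"] / by.loc["G1", "gH2AX_mean"] == \
            pytest.approx(2.0, rel=0.1)
        assert by.loc["G2", "p21_mean"] / by.loc["G1", "p21_mean"] == \
            pytest.approx(2.0, rel=0.1)

    def test_identical_means_give_equal_phase_summaries(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({
            "well_id": np.repeat([f"W{i}" for i in range(6)], 200),
            "phase": np.tile(["G1", "G2"], 600),
            "gH2AX_mean": rng.normal(500, 50, 1200),
        })
        out = summarize_markers_by_phase(rec)
        by = out.groupby("phase")["gH2AX_mean"].mean()
        assert by["G1"] == pytest.approx(by["G2"], rel=0.02)


class TestViability:
    def _platemap(self, condition="IR-G2-E", doses=(0.0, 1.0), n=3):
        wells = {}
        i = 0
        for d in doses:
            for _ in range(n):
                wells[f"W{i:02d}"] = {"condition": condition, "dose_uM": d}
                i += 1
        return PlateMap.from_dict(wells)

    def _counts(self, pm, count_fn):
        rows = []
        for w in pm.well_ids():
            n = count_fn(pm[w].dose_uM)
            rows.append({"well_id": w, "n_cells": n, "n_g1": n // 2,
                         "n_g2": n - n // 2})
        return pd.DataFrame(rows)

    def test_vehicle_group_mean_is_one(self):
        pm = self._platemap(doses=(0.0,), n=4)
        counts = self._counts(pm, lambda d: 1000)
        v = compute_viability(counts, pm)
        assert v["viability_total"].mean() == pytest.approx(1.0)

    def test_simple_ratio(self):
        pm = self._platemap(doses=(0.0, 1.0), n=1)
        counts = pd.DataFrame({
            "well_id": ["W00", "W01"], "n_cells": [1000, 400],
            "n_g1": [500, 300], "n_g2": [500, 100]})
        v = compute_viability(counts, pm).set_index("well_id")
        assert v.loc["W01", "viability_total"] == pytest.approx(0.4)
        assert v.loc["W01", "viability_g2"] == pytest.approx(0.2)

    def test_missing_vehicle_errors(self):
        pm = self._platemap(doses=(1.0,), n=3)
        counts = self._counts(pm, lambda d: 500)
        with pytest.raises(ValueError, match="vehicle"):
            compute_viability(counts, pm)

    def test_subpopulation_ratio_matches_exponential_kill(self):
        """viability_g2/viability_g1 ~ exp(-(k2-k1)*dose) from the truth model."""
        config = get_preset("IR-G2-E")
        params = DoseResponse(k_g1=0.25, k_g2=1.10)
        dose = 1.0
        pm = self._platemap(doses=(0.0, dose), n=10)
        rows = []
        rng = np.random.default_rng(8)
        for w in pm.well_ids():
            truth = sample_truth(config, 2000, rng, well_id=w, place=False)
            truth = apply_senolysis(truth, pm[w].dose_uM, params, rng)
            alive = truth[truth["alive"]]
            rows.append({
                "well_id": w, "n_cells": len(alive),
                "n_g1": int((alive["true_phase"] == "G1").sum()),
                "n_g2": int((alive["true_phase"] == "G2").sum())})
        v = compute_viability(pd.DataFrame(rows), pm)
        treated = v[v["dose_uM"] == dose]
        ratio = treated["viability_g2"].mean() / treated["viability_g1"].mean()
        expected = math.exp(-(params.k_g2 - params.k_g1) * dose)
        assert ratio == pytest.approx(expected, rel=0.05)


class TestIL6:
    def test_zero_concentration_gives_zero(self):
        df = pd.DataFrame({"il6_pg_per_ml": [0.0], "pooled_volume_ml": [0.2],
                           "pooled_cell_count": [4000]})
        assert normalize_il6(df)["il6_per_1000_cells"].iloc[0] == 0.0

    def test_handbook_arithmetic(self):
        """200 pg/mL in 0.15 mL over 3000 cells -> 10 pg per 1000 cells."""
        df = pd.DataFrame({"il6_pg_per_ml": [200.0], "pooled_volume_ml": [0.15],
                           "pooled_cell_count": [3000]})
        assert normalize_il6(df)["il6_per_1000_cells"].iloc[0] == pytest.approx(10.0)

    def test_linearity_and_inverse_count_scaling(self):
        base = pd.DataFrame({"il6_pg_per_ml": [100.0], "pooled_volume_ml": [0.2],
                             "pooled_cell_count": [2000]})
        doubled_conc = base.assign(il6_pg_per_ml=200.0)
        doubled_cells = base.assign(pooled_cell_count=4000)
        v0 = normalize_il6(base)["il6_per_1000_cells"].iloc[0]
        assert normalize_il6(doubled_conc)["il6_per_1000_cells"].iloc[0] == pytest.approx(2 * v0)
        assert normalize_il6(doubled_cells)["il6_per_1000_cells"].iloc[0] == pytest.approx(v0 / 2)

    def test_zero_cell_count_rejected(self):
        df = pd.DataFrame({"il6_pg_per_ml": [10.0], "pooled_volume_ml": [0.2],
                           "pooled_cell_count": [0]})
        with pytest.raises(ValueError):
            normalize_il6(df)

    def test_condition_ordering_recovered(self):
        """IR-G2-E secretes more IL-6 per cell than IR-G1-E than CTL."""
        samples = [(f"{cond}_{i}", cond, 3000, 0.15)
                   for cond in ("CTL", "IR-G1-E", "IR-G2-E") for i in range(4)]
        out = normalize_il6(simulate_secretion(samples, seed=0))
        by = out.groupby("condition")["il6_per_1000_cells"].mean()
        assert by["IR-G2-E"] > by["IR-G1-E"] > by["CTL"]
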
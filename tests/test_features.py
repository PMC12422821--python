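"""Feature tests: background rule, intensity/morphology extraction, foci, SA-β-Gal."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from senesceope import FieldImage, estimate_background, extract_features, count_foci, sabgal_od
from senesceope.features import FeatureParams
from senesceope.segmentation import LabelMask
from tests.conftest import match_to_truth


def _field_from(channels: dict, pixel_size=1.3):
    roles = {}
    planes = []
    for i, (role, img) in enumerate(channels.items()):
        roles[role] = i
        planes.append(np.asarray(img))
    return FieldImage(pixels=np.stack(planes).astype(np.uint16),
                      channel_roles=roles, pixel_size_um=pixel_size,
                      field_id="f", well_id="w")


def _disk_labels(shape=(128, 128), center=(64, 64), r=20):
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    labels[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r ** 2] = 1
    return LabelMask(labels)


class TestEstimateBackground:
    def test_constant_image(self):
        assert estimate_background(np.full((50, 50), 100.0)) == 100.0

    def test_matches_sorted_percentile_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.integers(0, 5000, size=rng.integers(10, 400))
            img = vals.reshape(1, -1).astype(float)
            # brute-force linear-interpolation percentile on the sorted multiset
            s = np.sort(vals.astype(float))
            h = 0.20 * (len(s) - 1)
            lo = int(math.floor(h))
            oracle = s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
            assert estimate_background(img) == pytest.approx(oracle, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1e5), min_size=2, max_size=60))
    def test_never_exceeds_median(self, values):
        img = np.asarray(values).reshape(1, -1)
        assert estimate_background(img) <= np.median(img) + 1e-9

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.empty((0,)))


class TestExtractFeatures:
    def test_digital_circle_morphology(self):
        """r=20 disk: shape factor ~1 (within discretization), aspect ~1."""
        mask = _disk_labels(r=20)
        img = np.full((128, 128), 50.0)
        img[mask.labels == 1] = 800.0
        field = _field_from({"dna": img})
        rec = extract_features(field, mask)
        assert len(rec) == 1
        assert 0.9 <= rec["shape_factor"].iloc[0] <= 1.05
        assert rec["aspect_ratio"].iloc[0] == pytest.approx(1.0, abs=0.05)
        assert rec["nuclear_area_um2"].iloc[0] == pytest.approx(
            math.pi * 20 ** 2 * 1.3 ** 2, rel=0.05)

    def test_shape_factor_scale_invariant(self):
        sf = []
        for r in (10, 30):
            mask = _disk_labels(shape=(128, 128), r=r)
            img = np.full((128, 128), 50.0)
            img[mask.labels == 1] = 800.0
            rec = extract_features(_field_from({"dna": img}), mask)
            sf.append(rec["shape_factor"].iloc[0])
        assert abs(sf[0] - sf[1]) < 0.06

    def test_uniform_nucleus_marker_mean_is_value_minus_background(self):
        mask = _disk_labels(r=15)
        dna = np.full((128, 128), 100.0)
        dna[mask.labels == 1] = 900.0
        p21 = np.full((128, 128), 80.0)
        p21[mask.labels == 1] = 680.0
        field = _field_from({"dna": dna, "p21": p21})
        rec = extract_features(field, mask)
        assert rec["p21_mean"].iloc[0] == pytest.approx(600.0, abs=1e-6)

    def test_integrated_dna_linear_in_signal(self):
        mask = _disk_labels(r=12)
        base = np.zeros((128, 128))
        base[mask.labels == 1] = 500.0
        one = extract_features(_field_from({"dna": base}), mask)
        two = extract_features(_field_from({"dna": 2 * base}), mask)
        assert two["integrated_dna"].iloc[0] == pytest.approx(
            2 * one["integrated_dna"].iloc[0], rel=1e-6)

    def test_integrated_dna_tracks_truth(self, ir_field_truth, ir_cells):
        _, _, truth = ir_field_truth
        matched, idx = match_to_truth(ir_cells, truth)
        measured = ir_cells["integrated_dna"].to_numpy()[matched]
        expected = truth["true_integrated_dna"].to_numpy()[idx[matched]]
        assert np.corrcoef(measured, expected)[0, 1] > 0.99

    def test_missing_channels_leave_features_absent(self):
        mask = _disk_labels(r=10)
        img = np.full((128, 128), 100.0)
        img[mask.labels == 1] = 700.0
        rec = extract_features(_field_from({"dna": img}), mask)
        assert "p21_mean" not in rec.columns
        assert "foci_count" not in rec.columns

    def test_empty_mask_returns_empty_frame(self):
        field = _field_from({"dna": np.full((64, 64), 100.0)})
        rec = extract_features(field, LabelMask(np.zeros((64, 64), dtype=np.int32)))
        assert rec.empty


class TestCountFoci:
    def _nucleus_with_spots(self, spots, amplitude=2000.0, sigma=1.5, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        img = np.full((128, 128), 300.0)
        if noise:
            img += rng.normal(0, noise, img.shape)
        yy, xx = np.mgrid[:128, :128]
        for (r, c) in spots:
            img += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
        mask = _disk_labels(shape=(128, 128), r=40)
        return _field_from({"dna": img, "gH2AX": img}), mask

    def test_flat_nucleus_has_no_foci(self):
        field, mask = self._nucleus_with_spots([])
        assert count_foci(field, mask)[0] == 0

    def test_five_planted_spots_counted(self):
        spots = [(50, 50), (50, 78), (64, 64), (78, 50), (78, 78)]
        field, mask = self._nucleus_with_spots(spots, noise=5.0)
        assert count_foci(field, mask)[0] == 5

    def test_single_pixel_spot_filtered_by_min_area(self):
        img = np.full((128, 128), 300.0)
        img[64, 64] += 3000.0  # area-1 spike
        mask = _disk_labels(shape=(128, 128), r=40)
        field = _field_from({"dna": img, "gH2AX": img})
        assert count_foci(field, mask)[0] == 0

    def test_noise_only_nuclei_rarely_fire(self):
        """Mean false-positive focus count stays below 0.1 at default k."""
        rng = np.random.default_rng(3)
        labels = np.zeros((512, 512), dtype=np.int32)
        yy, xx = np.mgrid[:512, :512]
        k = 0
        for r0 in range(40, 512, 90):
            for c0 in range(40, 512, 90):
                k += 1
                labels[(yy - r0) ** 2 + (xx - c0) ** 2 <= 18 ** 2] = k
        img = rng.normal(300, 12, (512, 512))
        field = _field_from({"dna": img, "gH2AX": img})
        counts = count_foci(field, LabelMask(labels))
        assert counts.mean() < 0.1


class TestSabgalOD:
    def _bf_field(self, od_in_region, i0=50000.0, r=15):
        mask = _disk_labels(r=r)
        bf = np.full((128, 128), i0)
        bf[mask.labels == 1] = i0 * 10 ** (-od_in_region)
        dna = np.full((128, 128), 100.0)
        return _field_from({"dna": dna, "brightfield_sabgal": bf}), mask

    def test_no_absorbance_gives_zero(self):
        field, mask = self._bf_field(0.0)
        assert sabgal_od(field, mask)[1] == pytest.approx(0.0, abs=1e-6)

    def test_tenfold_attenuation_gives_od_one(self):
        field, mask = self._bf_field(1.0)
        assert sabgal_od(field, mask)[1] == pytest.approx(1.0, abs=0.01)

    def test_generator_od_recovered(self, ir_field_truth, ir_segmentation, ir_cells):
        """Rendered cells recover their known OD within 5% relative error."""
        config, _, truth = ir_field_truth
        matched, idx = match_to_truth(ir_cells, truth)
        od = ir_cells["sabgal_od"].to_numpy()[matched]
        expected = truth["true_sabgal_od"].to_numpy()[idx[matched]]
        rel = np.abs(od - expected) / expected
        assert np.median(rel) < 0.05
        assert abs(od.mean() / expected.mean() - 1) < 0.05
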
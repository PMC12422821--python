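"""Synthetic microscopy plate generator with per-cell ground truth.

Emulates wide-field acquisition of DAPI plus up to four nuclear marker
channels and an absorbance-style SA-β-Gal brightfield channel: 16-bit
1024×1024 fields at 1.3 µm/pixel, nuclei rendered as anisotropic
Gaussian-profile ellipses, Poisson photon shot noise plus Gaussian read noise,
and a constant-pedestal-plus-linear-gradient fluorescence background.  Every
rendered cell has a matching ground-truth row (latent phase, integrated DNA,
marker means, focus count, SA-β-Gal optical density, alive flag), so each
downstream analysis stage can be validated against known truth.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import MARKER_ROLES, DoseResponse, GeneratorConfig, get_preset
from .io import FieldImage, PlateMap

TRUTH_MARKER_COLS = [f"true_{m}_mean" for m in MARKER_ROLES]

TRUTH_COLUMNS = [
    "cell_id", "field_id", "well_id", "centroid_row", "centroid_col",
    "true_phase", "true_integrated_dna", "area_px2", "axis_ratio", "theta",
    "semi_a", "semi_b", *TRUTH_MARKER_COLS,
    "true_foci_count", "true_sabgal_od", "edu_positive", "alive",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def sample_truth(
    config: GeneratorConfig,
    n_cells: int,
    rng,
    field_id: str = "F00",
    well_id: str = "W00",
    place: bool = True,
) -> pd.DataFrame:
    """Draw per-cell latent truth (phase, geometry, levels) and place nuclei.

    Placement uses rejection sampling with a minimum centroid spacing; if a
    cell cannot be placed within ``config.max_place_tries`` attempts the count
    is reduced with a warning.  ``place=False`` skips the spacing constraint
    (uniform centroids) for truth-only studies that never render images.
    """
    rng = _as_rng(rng)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")

    # latent cell-cycle phase
    p_g2 = config.g2_true_fraction
    u = rng.random(n_cells)
    phase = np.where(u < config.s_fraction, "S",
                     np.where(u < config.s_fraction + p_g2, "G2", "G1"))

    # geometry
    area = _lognormal(rng, config.nuclear_area_px2, config.nuclear_area_cv, n_cells)
    ratio = rng.uniform(1.0, config.axis_ratio_max, n_cells)
    theta = rng.uniform(0.0, math.pi, n_cells)
    semi_b = np.sqrt(area / (math.pi * ratio))
    semi_a = semi_b * ratio

    # integrated DNA: G1 lognormal, G2 doubled, S uniform multiplier in [1, 2]
    dna = _lognormal(rng, config.dna_g1_mean, config.dna_cv, n_cells)
    dna = np.where(phase == "G2", 2.0 * dna, dna)
    s_mask = phase == "S"
    if s_mask.any():
        dna[s_mask] *= rng.uniform(1.0, 2.0, int(s_mask.sum()))

    # marker levels
    edu_prob = np.array([config.edu_positive_prob.get(p, 0.0) for p in phase])
    edu_positive = rng.random(n_cells) < edu_prob
    marker_means = {}
    for role in MARKER_ROLES:
        params = config.marker_params.get(role)
        if role == "edu":
            base = np.where(edu_positive, config.edu_positive_level,
                            config.edu_negative_level)
            cv = params.cv if params is not None else 0.3
            noise = _lognormal(rng, 1.0, cv, n_cells)
            marker_means[role] = base * noise
        elif params is None:
            marker_means[role] = np.zeros(n_cells)
        else:
            mean = np.array([params.mean_for(p) for p in phase])
            marker_means[role] = mean * _lognormal(rng, 1.0, params.cv, n_cells)

    lam = np.where(phase == "G2", config.foci_lambda_g2, config.foci_lambda_g1)
    foci = rng.poisson(lam)
    sabgal = _lognormal(rng, config.sabgal_od_mean, config.sabgal_od_cv, n_cells) \
        if config.sabgal_od_mean > 0 else np.zeros(n_cells)

    # placement with non-overlap rejection sampling (vectorized spacing check)
    size = config.image_size
    if place:
        min_sp2 = config.min_spacing_px ** 2
        placed_r = np.empty(n_cells)
        placed_c = np.empty(n_cells)
        n_placed = 0
        kept = []
        for i in range(n_cells):
            pad = semi_a[i] + 3.0
            if 2 * pad >= size:
                continue
            placed = False
            for _ in range(config.max_place_tries):
                r = rng.uniform(pad, size - pad)
                c = rng.uniform(pad, size - pad)
                d2 = (placed_r[:n_placed] - r) ** 2 + (placed_c[:n_placed] - c) ** 2
                if not (d2 < min_sp2).any():
                    placed_r[n_placed] = r
                    placed_c[n_placed] = c
                    n_placed += 1
                    kept.append(i)
                    placed = True
                    break
            if not placed:
                warnings.warn(
                    f"placement failed after {config.max_place_tries} tries; "
                    f"rendering {len(kept)} of {n_cells} cells", stacklevel=2)
                break
        rows = placed_r[:n_placed]
        cols = placed_c[:n_placed]
        kept = np.asarray(kept, dtype=int)
    else:
        rows = rng.uniform(0.0, size, n_cells)
        cols = rng.uniform(0.0, size, n_cells)
        kept = np.arange(n_cells)
    truth = pd.DataFrame({
        "cell_id": [f"{well_id}_{field_id}_{k:04d}" for k in range(len(kept))],
        "field_id": field_id,
        "well_id": well_id,
        "centroid_row": np.asarray(rows),
        "centroid_col": np.asarray(cols),
        "true_phase": phase[kept],
        "true_integrated_dna": dna[kept],
        "area_px2": area[kept],
        "axis_ratio": ratio[kept],
        "theta": theta[kept],
        "semi_a": semi_a[kept],
        "semi_b": semi_b[kept],
        **{f"true_{m}_mean": marker_means[m][kept] for m in MARKER_ROLES},
        "true_foci_count": foci[kept],
        "true_sabgal_od": sabgal[kept],
        "edu_positive": edu_positive[kept],
        "alive": True,
    })
    return truth[TRUTH_COLUMNS]


def _ellipse_profile(config, row, cell, expand: float = 0.0):
    """Return (row slice, col slice, normalized distance patch) for one cell."""
    a = cell.semi_a + expand
    b = cell.semi_b + expand
    r0, c0 = cell.centroid_row, cell.centroid_col
    half = a + 1.0
    size = config.image_size
    r_lo, r_hi = max(int(r0 - half), 0), min(int(r0 + half) + 2, size)
    c_lo, c_hi = max(int(c0 - half), 0), min(int(c0 + half) + 2, size)
    rr = np.arange(r_lo, r_hi)[:, None] - r0
    cc = np.arange(c_lo, c_hi)[None, :] - c0
    ct, st = math.cos(cell.theta), math.sin(cell.theta)
    u = ct * cc + st * rr
    v = -st * cc + ct * rr
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return slice(r_lo, r_hi), slice(c_lo, c_hi), d


def truth_footprints(config: GeneratorConfig, truth: pd.DataFrame) -> np.ndarray:
    """Label image of the true nuclear footprints (1-based, row order)."""
    labels = np.zeros((config.image_size, config.image_size), dtype=np.int32)
    for k, cell in enumerate(truth.itertuples(), start=1):
        rs, cs, d = _ellipse_profile(config, None, cell)
        patch = labels[rs, cs]
        patch[d <= 1.0] = k
    return labels


def render_field(
    config: GeneratorConfig,
    truth: pd.DataFrame,
    rng,
    field_id: str = "F00",
    well_id: str = "W00",
) -> FieldImage:
    """Render the alive cells of a truth table into a multi-channel field."""
    rng = _as_rng(rng)
    size = config.image_size
    s = config.profile_softness
    p = config.profile_exponent

    fluor_roles = ["dna", *[c for c in config.channels if c in MARKER_ROLES]]
    if len(fluor_roles) > 5:
        raise ValueError("at most 4 marker channels besides DNA are supported")
    planes = {role: np.zeros((size, size), dtype=np.float64) for role in fluor_roles}
    od_map = np.zeros((size, size), dtype=np.float64) if config.include_brightfield else None

    alive = truth[truth["alive"]]
    for cell in alive.itertuples():
        rs, cs, d = _ellipse_profile(config, None, cell)
        inside = d <= 1.0
        if not inside.any():
            continue
        profile = np.where(inside, np.exp(-0.5 * (d / s) ** p), 0.0)
        psum = profile.sum()
        npx = int(inside.sum())

        planes["dna"][rs, cs] += profile * (cell.true_integrated_dna / psum)
        for role in fluor_roles[1:]:
            level = getattr(cell, f"true_{role}_mean")
            if level > 0:
                planes[role][rs, cs] += profile * (level * npx / psum)

        if "gH2AX" in planes and cell.true_foci_count > 0:
            _add_foci(planes["gH2AX"], config, cell, rng)

        if od_map is not None and cell.true_sabgal_od > 0:
            # chromogenic deposit reaches slightly beyond the measured cell
            # region so the region mean recovers the per-cell OD without
            # rim dilution
            ers, ecs, ed = _ellipse_profile(
                config, None, cell, expand=config.cell_expand_px + 2.0)
            # adjacent halos do not stack: a pixel reports the densest deposit
            od_map[ers, ecs] = np.maximum(
                od_map[ers, ecs], np.where(ed <= 1.0, cell.true_sabgal_od, 0.0))

    # background, shot noise and read noise
    gdir = rng.uniform(0.0, 2 * math.pi)
    gx, gy = math.cos(gdir), math.sin(gdir)
    ramp = (np.arange(size)[:, None] * gy + np.arange(size)[None, :] * gx) / size
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
    bg = config.background_level + config.background_gradient * ramp

    stack, roles = [], {}
    for idx, role in enumerate(fluor_roles):
        img = planes[role] + bg
        noisy = rng.poisson(img).astype(np.float64)
        noisy += rng.normal(0.0, config.read_noise_sd, noisy.shape)
        stack.append(np.clip(np.round(noisy), 0, 65535).astype(np.uint16))
        roles[role] = idx

    if od_map is not None:
        i0 = config.brightfield_i0_frac * 65535.0
        bf = i0 * np.power(10.0, -od_map)
        noisy = rng.poisson(bf).astype(np.float64)
        noisy += rng.normal(0.0, config.read_noise_sd, noisy.shape)
        roles["brightfield_sabgal"] = len(stack)
        stack.append(np.clip(np.round(noisy), 0, 65535).astype(np.uint16))

    return FieldImage(
        pixels=np.stack(stack),
        channel_roles=roles,
        pixel_size_um=config.pixel_size_um,
        field_id=field_id,
        well_id=well_id,
    )


def _add_foci(plane: np.ndarray, config: GeneratorConfig, cell, rng) -> None:
    """Plant Poisson-count gammaH2AX foci inside the nuclear footprint."""
    sigma = config.foci_sigma_px
    positions: list[tuple[float, float]] = []
    min_d2 = (3.0 * sigma) ** 2
    for _ in range(int(cell.true_foci_count)):
        for _ in range(50):
            d = math.sqrt(rng.uniform(0.0, 0.75 ** 2))
            ang = rng.uniform(0.0, 2 * math.pi)
            u = d * math.cos(ang) * cell.semi_a
            v = d * math.sin(ang) * cell.semi_b
            ct, st = math.cos(cell.theta), math.sin(cell.theta)
            r = cell.centroid_row + st * u + ct * v
            c = cell.centroid_col + ct * u - st * v
            if all((r - rr) ** 2 + (c - cc) ** 2 >= min_d2 for rr, cc in positions):
                positions.append((r, c))
                break
    half = int(math.ceil(3 * sigma))
    size = plane.shape[0]
    for r0, c0 in positions:
        r_lo, r_hi = max(int(r0) - half, 0), min(int(r0) + half + 2, size)
        c_lo, c_hi = max(int(c0) - half, 0), min(int(c0) + half + 2, size)
        rr = np.arange(r_lo, r_hi)[:, None] - r0
        cc = np.arange(c_lo, c_hi)[None, :] - c0
        plane[r_lo:r_hi, c_lo:c_hi] += config.foci_amplitude * np.exp(
            -(rr ** 2 + cc ** 2) / (2 * sigma ** 2))


def generate_field(
    config: GeneratorConfig,
    n_cells: int | None = None,
    rng=None,
    field_id: str = "F00",
    well_id: str = "W00",
) -> tuple[FieldImage, pd.DataFrame]:
    """Generate one field and its ground-truth table.

    ``n_cells`` defaults to a Poisson draw around ``config.cells_per_field``.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if n_cells is None:
        n_cells = int(rng.poisson(config.cells_per_field))
    truth = sample_truth(config, n_cells, rng, field_id=field_id, well_id=well_id)
    field = render_field(config, truth, rng, field_id=field_id, well_id=well_id)
    return field, truth


def apply_senolysis(
    truth: pd.DataFrame,
    dose_uM: float,
    params: DoseResponse | None = None,
    rng=None,
) -> pd.DataFrame:
    """Kill alive cells independently with per-phase exponential survival.

    Survival is s_phase(d) = exp(-k_phase * d) with k_G2 > k_G1 by default
    (G2-arrested senescent cells are the more senolytic-susceptible).  Returns
    a copy with updated ``alive`` flags; dose 0 kills nothing.
    """
    if dose_uM < 0:
        raise ValueError("dose must be >= 0")
    params = params or DoseResponse()
    rng = _as_rng(rng)
    out = truth.copy()
    if dose_uM == 0 or len(out) == 0:
        return out
    k = np.array([params.k_for(p) for p in out["true_phase"]])
    survive_p = np.exp(-k * dose_uM)
    survive = rng.random(len(out)) < survive_p
    out["alive"] = out["alive"].to_numpy() & survive
    return out


def well_seed_sequence(master_seed: int, well_index: int, field_index: int | None = None):
    """Reproducible per-well / per-field seed derivation from a master seed."""
    key = (well_index,) if field_index is None else (well_index, field_index)
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def generate_plate(
    design: PlateMap,
    config_overrides: dict[str, GeneratorConfig] | None = None,
    seed: int = 0,
    n_fields_per_well: int = 4,
    render: bool = True,
) -> list[tuple[FieldImage | None, pd.DataFrame]]:
    """Generate all fields of a plate described by a plate map.

    Each well uses the preset named by its condition (or an override config),
    applies the senolytic model at the well's dose, and renders the surviving
    cells.  Per-well/field seeds derive reproducibly from ``seed``; the same
    seed yields byte-identical plates.  With ``render=False`` only truth
    tables are produced (fields are ``None``).
    """
    config_overrides = config_overrides or {}
    out: list[tuple[FieldImage | None, pd.DataFrame]] = []
    for wi, well_id in enumerate(design.well_ids()):
        info = design[well_id]
        config = config_overrides.get(info.condition) or get_preset(info.condition)
        for fi in range(n_fields_per_well):
            rng = np.random.default_rng(well_seed_sequence(seed, wi, fi))
            field_id = f"{well_id}_f{fi:02d}"
            n = int(rng.poisson(config.cells_per_field))
            truth = sample_truth(config, n, rng, field_id=field_id, well_id=well_id)
            truth = apply_senolysis(truth, info.dose_uM, config.dose_response, rng)
            field = (
                render_field(config, truth, rng, field_id=field_id, well_id=well_id)
                if render else None
            )
            out.append((field, truth))
    return out


def make_platemap(
    conditions: Sequence[str],
    n_wells: int,
    doses: Sequence[float] = (0.0,),
    serum_state: str = "FS",
) -> PlateMap:
    """Convenience plate-map builder: ``n_wells`` wells per condition x dose."""
    wells = {}
    idx = 0
    for cond in conditions:
        for dose in doses:
            for rep in range(n_wells):
                wells[f"W{idx:03d}"] = {
                    "condition": cond, "dose_uM": float(dose),
                    "serum_state": serum_state, "replicate": rep + 1,
                }
                idx += 1
    return PlateMap.from_dict(wells)


def simulate_secretion(
    samples: Iterable[tuple[str, str, int, float]],
    seed: int = 0,
    noise_cv: float = 0.15,
) -> pd.DataFrame:
    """Simulate pooled-conditioned-medium IL-6 ELISA inputs.

    ``samples`` yields (sample_id, condition, pooled_cell_count, volume_ml);
    the measured concentration is rate(condition) x cells/1000 / volume with
    lognormal assay noise.  Output feeds ``endpoints.normalize_il6``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, condition, cells, volume_ml in samples:
        rate = get_preset(condition).il6_rate_pg_per_1000cells
        conc = rate * (cells / 1000.0) / volume_ml
        conc *= float(_lognormal(rng, 1.0, noise_cv, 1)[0])
        rows.append({
            "sample_id": sample_id, "condition": condition,
            "il6_pg_per_ml": conc, "pooled_volume_ml": volume_ml,
            "pooled_cell_count": cells,
        })
    return pd.DataFrame(rows)
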
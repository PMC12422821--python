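"""Configuration objects and condition presets for the synthetic plate generator.

The presets encode the culture conditions of the radiation-induced senescence
model: mock-irradiated controls (CTL) and irradiated senescent populations (IR)
of primary endothelial cells, each optionally enriched in G1 (serum starvation
before irradiation) or G2 (exponential growth at irradiation).  ``IR-FIBRO`` is
a senescent-fibroblast-like preset that differs from the endothelial ``IR``
preset mainly in its SA-β-Gal absorbance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

#: probability that a mid-S cell (DNA content uniform on [1x, 2x]) falls above
#: the geometric-mean boundary sqrt(2) between the G1 and G2 modes
_S_ABOVE_BOUNDARY = 2.0 - math.sqrt(2.0)

MARKER_ROLES = ("edu", "gH2AX", "p21", "laminB1", "hmgb1")


@dataclass(frozen=True)
class MarkerParams:
    """Per-channel nuclear intensity model: mean level by phase plus lognormal CV."""

    mean_g1: float
    mean_g2: float
    cv: float = 0.30

    def mean_for(self, phase: str) -> float:
        if phase == "G2":
            return self.mean_g2
        # S cells are only present in proliferating controls; their marker
        # levels interpolate between the phase means.
        if phase == "S":
            return 0.5 * (self.mean_g1 + self.mean_g2)
        return self.mean_g1


@dataclass(frozen=True)
class DoseResponse:
    """Per-phase exponential senolytic kill model s_phase(d) = exp(-k_phase * d)."""

    k_g1: float = 0.25  # 1/uM
    k_g2: float = 1.10  # 1/uM

    def k_for(self, phase: str) -> float:
        return self.k_g2 if phase == "G2" else self.k_g1


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of one synthetic condition.

    Intensities are in raw camera units of a 16-bit detector; geometry is in
    pixels at ``pixel_size_um`` per pixel.
    """

    condition: str = "IR"
    image_size: int = 1024
    pixel_size_um: float = 1.3
    cells_per_field: int = 500

    # cell-cycle composition; g2_fraction is the expected *gated* two-class G2
    # call rate (see g2_true_fraction for the latent true-G2 probability)
    g2_fraction: float = 0.45
    s_fraction: float = 0.0

    # integrated-DAPI model: G1 cells are lognormal with this mean and CV;
    # G2 cells are 2x; S cells multiply a G1 draw by U(1, 2)
    dna_g1_mean: float = 2.0e5
    dna_cv: float = 0.12

    # nuclear geometry (senescent nuclei are enlarged vs control)
    nuclear_area_px2: float = 280.0
    nuclear_area_cv: float = 0.22
    axis_ratio_max: float = 1.6

    marker_params: Mapping[str, MarkerParams] = field(default_factory=dict)
    channels: tuple[str, ...] = ("edu", "gH2AX", "p21", "laminB1")
    include_brightfield: bool = True

    # gammaH2AX focus model
    foci_lambda_g1: float = 6.0
    foci_lambda_g2: float = 10.0
    foci_amplitude: float = 1500.0
    foci_sigma_px: float = 1.5

    # EdU-positivity probability by phase (truth labels driving the EdU level)
    edu_positive_prob: Mapping[str, float] = field(default_factory=dict)
    edu_positive_level: float = 800.0
    edu_negative_level: float = 2.0

    # SA-beta-Gal absorbance
    sabgal_od_mean: float = 0.25
    sabgal_od_cv: float = 0.20
    cell_expand_px: int = 6
    brightfield_i0_frac: float = 0.80

    # IL-6 secretion rate, pg per 1000 cells over the 48 h collection window
    il6_rate_pg_per_1000cells: float = 10.0

    # imaging noise/background model; nuclei render as flat-top
    # "super-Gaussian" plateaus exp(-0.5*(d/softness)^exponent) truncated at
    # the ellipse boundary d=1
    background_level: float = 100.0
    background_gradient: float = 10.0
    read_noise_sd: float = 2.0
    profile_softness: float = 0.85
    profile_exponent: float = 6.0

    # placement
    min_spacing_factor: float = 2.6
    max_place_tries: int = 200

    dose_response: DoseResponse = field(default_factory=DoseResponse)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.g2_fraction <= 1.0:
            raise ValueError("g2_fraction must be in [0, 1]")
        if self.g2_fraction + self.s_fraction > 1.0 + 1e-12:
            raise ValueError("g2_fraction + s_fraction must be <= 1")
        if self.dna_cv <= 0 or self.nuclear_area_cv <= 0:
            raise ValueError("all CVs must be > 0")
        if self.dna_g1_mean <= 0:
            raise ValueError("dna_g1_mean must be > 0")

    @property
    def g2_true_fraction(self) -> float:
        """Latent probability a cell is truly G2.

        The preset ``g2_fraction`` is the expected two-class G2 call rate; mid-S
        cells land above the boundary with probability 2-sqrt(2), so the latent
        G2 draw is reduced accordingly.
        """
        p = self.g2_fraction - self.s_fraction * _S_ABOVE_BOUNDARY
        return min(max(p, 0.0), 1.0 - self.s_fraction)

    @property
    def min_spacing_px(self) -> float:
        mean_radius = math.sqrt(self.nuclear_area_px2 / math.pi)
        return self.min_spacing_factor * mean_radius

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _markers(gh2ax, p21, laminb1, hmgb1) -> dict[str, MarkerParams]:
    return {
        "edu": MarkerParams(0.0, 0.0, 0.3),  # level set by the EdU-positivity flag
        "gH2AX": MarkerParams(*gh2ax),
        "p21": MarkerParams(*p21),
        "laminB1": MarkerParams(*laminb1),
        "hmgb1": MarkerParams(*hmgb1),
    }


# Senescent cells carry higher gammaH2AX/p21 and lower LaminB1/HMGB1 than
# controls; within senescent populations the G2-arrested cells express more of
# the positive markers and retain less of the inverse markers.
_CTL_MARKERS = _markers((60, 120, 0.3), (100, 150, 0.3), (600, 600, 0.25), (600, 600, 0.25))
_IR_MARKERS = _markers((300, 600, 0.3), (400, 800, 0.3), (250, 175, 0.25), (300, 210, 0.25))

_CTL_BASE = dict(
    nuclear_area_px2=160.0,
    marker_params=_CTL_MARKERS,
    foci_lambda_g1=0.3,
    foci_lambda_g2=0.5,
    sabgal_od_mean=0.02,
    il6_rate_pg_per_1000cells=2.0,
)
_IR_BASE = dict(
    nuclear_area_px2=280.0,
    marker_params=_IR_MARKERS,
    foci_lambda_g1=6.0,
    foci_lambda_g2=10.0,
    sabgal_od_mean=0.25,
)

_PROLIF_EDU = {"G1": 0.4, "S": 1.0, "G2": 0.9}
_ARRESTED_EDU = {"G1": 0.0, "S": 0.0, "G2": 0.0}

#: condition presets; G2 call-rate targets follow the enrichment protocol
#: (~40% vs ~20% G2 just before irradiation, ~60% vs ~30% after senescence)
PRESETS: dict[str, GeneratorConfig] = {
    "CTL": GeneratorConfig(
        condition="CTL", g2_fraction=0.30, s_fraction=0.10,
        edu_positive_prob=_PROLIF_EDU, **_CTL_BASE,
    ),
    "CTL-G1-E": GeneratorConfig(
        condition="CTL-G1-E", g2_fraction=0.20, s_fraction=0.0,
        edu_positive_prob=_ARRESTED_EDU, **_CTL_BASE,
    ),
    "CTL-G2-E": GeneratorConfig(
        condition="CTL-G2-E", g2_fraction=0.40, s_fraction=0.10,
        edu_positive_prob=_PROLIF_EDU, **_CTL_BASE,
    ),
    "IR": GeneratorConfig(
        condition="IR", g2_fraction=0.45, s_fraction=0.0,
        edu_positive_prob=_ARRESTED_EDU, **_IR_BASE,
    ),
    "IR-G1-E": GeneratorConfig(
        condition="IR-G1-E", g2_fraction=0.30, s_fraction=0.0,
        edu_positive_prob=_ARRESTED_EDU, il6_rate_pg_per_1000cells=10.0, **_IR_BASE,
    ),
    "IR-G2-E": GeneratorConfig(
        condition="IR-G2-E", g2_fraction=0.60, s_fraction=0.0,
        edu_positive_prob=_ARRESTED_EDU, il6_rate_pg_per_1000cells=25.0, **_IR_BASE,
    ),
    # senescent fibroblast-like population: ~5x lower SA-beta-Gal absorbance
    # than the senescent endothelial-like IR preset
    "IR-FIBRO": GeneratorConfig(
        condition="IR-FIBRO", g2_fraction=0.45, s_fraction=0.0,
        edu_positive_prob=_ARRESTED_EDU,
        nuclear_area_px2=340.0,
        marker_params=_markers((250, 500, 0.3), (600, 1100, 0.3), (250, 175, 0.25), (300, 210, 0.25)),
        foci_lambda_g1=6.0, foci_lambda_g2=10.0,
        sabgal_od_mean=0.05,
    ),
}


def get_preset(name: str) -> GeneratorConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition preset {name!r}; known: {sorted(PRESETS)}"
        ) from None
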
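"""Per-cell feature extraction: intensities, DNA content, foci, SA-β-Gal, morphology.

All fluorescence readouts are background-corrected with the 20th-percentile
rule, estimated per field and per channel.  Marker means use the nuclear mask
(all ICC markers here are nuclear); SA-β-Gal optical density uses the expanded
cell region because the lysosomal stain is cytoplasmic.

Shape factor is circularity 4πA/P² (1 for a perfect disk); perimeter uses the
Crofton boundary estimate, which is close to unbiased for smooth digital
shapes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table
from skimage.morphology import disk, white_tophat

logger = logging.getLogger(__name__)

BACKGROUND_PERCENTILE = 20.0

MARKER_FEATURES = ("edu", "gH2AX", "p21", "laminB1", "hmgb1")


@dataclass(frozen=True)
class FeatureParams:
    foci_tophat_radius_px: int = 3
    foci_mad_k: float = 5.0
    foci_min_area_px: int = 2
    foci_max_area_px: int = 50


def estimate_background(channel: np.ndarray) -> float:
    """Fluorescence background: the 20th percentile of the intensity histogram.

    Uses the linear-interpolation percentile convention.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("cannot estimate background of an empty image")
    return float(np.percentile(channel, BACKGROUND_PERCENTILE))


def extract_features(
    field,
    nuclei,
    cell_regions=None,
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Extract one row of per-cell features per segmented nucleus.

    integrated_dna is the background-corrected DAPI sum over the nuclear mask
    (negative pixels clipped at 0); marker features are background-corrected
    nuclear means.  Morphology: area (µm²), Crofton perimeter (µm), shape
    factor 4πA/P², and aspect ratio of the best-fit ellipse.  Missing channel
    roles simply leave their features absent (logged once).
    """
    params = params or FeatureParams()
    labels = nuclei.labels
    if labels.shape != field.shape:
        raise ValueError("nuclei mask does not match image dimensions")
    n = int(labels.max())
    px = field.pixel_size_um

    if n == 0:
        return pd.DataFrame()

    dna = field.channel("dna").astype(np.float64)
    bg = estimate_background(dna)
    dna_corr = np.clip(dna - bg, 0.0, None)

    props = regionprops_table(
        labels,
        properties=(
            "label", "centroid", "area", "perimeter_crofton",
            "axis_major_length", "axis_minor_length",
        ),
    )
    area_px2 = props["area"].astype(float)
    perimeter_px = props["perimeter_crofton"].astype(float)
    minor = np.maximum(props["axis_minor_length"].astype(float), 1e-9)

    index = np.arange(1, n + 1)
    records = pd.DataFrame({
        "cell_id": [f"{field.well_id}_{field.field_id}_{k:04d}" for k in index],
        "label": props["label"].astype(int),
        "well_id": field.well_id,
        "field_id": field.field_id,
        "centroid_row": props["centroid-0"],
        "centroid_col": props["centroid-1"],
        "nuclear_area_um2": area_px2 * px * px,
        "perimeter_um": perimeter_px * px,
        "shape_factor": 4.0 * math.pi * area_px2 / np.maximum(perimeter_px, 1e-9) ** 2,
        "aspect_ratio": props["axis_major_length"].astype(float) / minor,
        "integrated_dna": ndi.sum_labels(dna_corr, labels, index=index),
    })

    missing = []
    for role in MARKER_FEATURES:
        if not field.has_channel(role):
            missing.append(role)
            continue
        chan = field.channel(role).astype(np.float64)
        chan_bg = estimate_background(chan)
        records[f"{role}_mean"] = ndi.mean(chan - chan_bg, labels, index=index)
    if missing:
        logger.debug("field %s: channels absent, features skipped: %s",
                     field.field_id, ", ".join(missing))

    if field.has_channel("gH2AX"):
        records["foci_count"] = count_foci(field, nuclei, "gH2AX", params)
    if field.has_channel("brightfield_sabgal") and cell_regions is not None:
        od = sabgal_od(field, cell_regions)
        records["sabgal_od"] = records["label"].map(od).to_numpy()

    records["phase"] = pd.Series(pd.NA, index=records.index, dtype="string")
    return records


def count_foci(field, nuclei, channel_role: str = "gH2AX",
               params: FeatureParams | None = None) -> np.ndarray:
    """Count bright sub-nuclear foci per nucleus.

    White top-hat (disk radius 3 px) isolates puncta; within each nucleus a
    robust threshold at median + k·MAD of the top-hat signal selects candidate
    pixels, and connected components with area in [2, 50] px are counted.
    """
    params = params or FeatureParams()
    labels = nuclei.labels
    n = int(labels.max())
    if n == 0:
        return np.zeros(0, dtype=int)
    chan = field.channel(channel_role).astype(np.float64)
    tophat = white_tophat(chan, footprint=disk(params.foci_tophat_radius_px))

    counts = np.zeros(n, dtype=int)
    objects = ndi.find_objects(labels)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = labels[sl] == k
        vals = tophat[sl][region]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        th = med + params.foci_mad_k * max(mad, 1e-9)
        cand = (tophat[sl] > th) & region
        comp, n_comp = ndi.label(cand)
        if n_comp == 0:
            continue
        areas = ndi.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
        counts[k - 1] = int(np.sum(
            (areas >= params.foci_min_area_px) & (areas <= params.foci_max_area_px)))
    return counts


def sabgal_od(field, cell_regions) -> dict[int, float]:
    """Per-cell mean SA-β-Gal optical density from the brightfield channel.

    I0 is the median brightfield intensity over background pixels (label 0);
    per-cell OD is the mean of −log10(max(I, 1)/I0) over the cell region,
    clipped at 0.
    """
    labels = cell_regions.labels
    bf = field.channel("brightfield_sabgal").astype(np.float64)
    if labels.shape != bf.shape:
        raise ValueError("cell-region mask does not match image dimensions")
    background = bf[labels == 0]
    if background.size == 0:
        raise ValueError("no background pixels to estimate I0 from")
    i0 = float(np.median(background))
    if i0 <= 0:
        raise ValueError("non-positive brightfield reference intensity I0")
    od_img = -np.log10(np.maximum(bf, 1.0) / i0)
    n = int(labels.max())
    if n == 0:
        return {}
    means = ndi.mean(od_img, labels, index=np.arange(1, n + 1))
    return {k: float(max(v, 0.0)) for k, v in zip(range(1, n + 1), means)}
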
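"""Nuclei segmentation from the DAPI channel and perinuclear region expansion.

The segmentation design is deliberately standard and fully parameterized:
background subtraction (20th-percentile rule), Gaussian smoothing, global Otsu
threshold, hole filling, distance-transform watershed to split touching
nuclei, then area and border filtering.  Adequate for non-confluent cultures;
every threshold is exposed in :class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.segmentation import relabel_sequential, watershed

from .features import estimate_background


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma_px: float = 0.6
    min_area_px: int = 80
    max_area_px: int = 8000
    peak_min_distance_px: int = 10
    discard_border: bool = True


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k > 0 = nucleus/cell k."""

    labels: np.ndarray
    field_id: str = ""

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def segment_nuclei(
    dna_channel: np.ndarray,
    params: SegmentationParams | None = None,
    field_id: str = "",
) -> LabelMask:
    """Segment nuclei in a single DAPI image.

    Border-touching nuclei are discarded by default: their integrated DNA
    content would be truncated and corrupt the G1/G2 gate.  An empty or blank
    image yields an empty mask, not an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(dna_channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("dna_channel must be a single 2-D image")

    bg = estimate_background(img)
    corrected = np.clip(img - bg, 0.0, None)
    smoothed = gaussian(corrected, sigma=params.smoothing_sigma_px, preserve_range=True)

    # Otsu on the log-compressed image: nuclear brightness spans an order of
    # magnitude (2N vs 4N DNA, staining variability), and a threshold chosen on
    # the linear scale erodes dim nuclei much more than bright ones
    log_img = np.log1p(smoothed)
    try:
        th = threshold_otsu(log_img)
    except ValueError:  # constant image
        return LabelMask(np.zeros_like(img, dtype=np.int32), field_id)
    binary = log_img > th
    if not binary.any():
        return LabelMask(np.zeros_like(img, dtype=np.int32), field_id)
    binary = ndi.binary_fill_holes(binary)

    # smoothing the distance map keeps elongated nuclei from sprouting several
    # ridge maxima and being over-split
    distance = ndi.distance_transform_edt(binary)
    distance_s = gaussian(distance, sigma=2.0, preserve_range=True)
    peaks = peak_local_max(
        distance_s,
        min_distance=params.peak_min_distance_px,
        labels=binary,
        exclude_border=False,
    )
    peak_img = np.zeros_like(binary)
    peak_img[tuple(peaks.T)] = True
    markers, _ = ndi.label(peak_img)
    labels = watershed(-distance_s, markers, mask=binary, connectivity=1)

    labels = _filter_regions(labels, params)
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels.astype(np.int32), field_id)


def _filter_regions(labels: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if labels.max() == 0:
        return labels
    n = labels.max()
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    bad = (areas < params.min_area_px) | (areas > params.max_area_px)
    if params.discard_border:
        border = np.zeros(n, dtype=bool)
        for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
            touched = np.unique(edge)
            touched = touched[touched > 0]
            border[touched - 1] = True
        bad |= border
    if bad.any():
        labels = labels.copy()
        labels[np.isin(labels, np.nonzero(bad)[0] + 1)] = 0
    return labels


def expand_to_cell_region(mask: LabelMask, radius_px: int) -> LabelMask:
    """Expand each nucleus by ``radius_px`` to a cell-region proxy.

    Geodesic expansion: every background pixel within reach is assigned to its
    nearest nucleus (Euclidean distance), so adjacent regions stay disjoint and
    partition the contact zone; nuclear pixels keep their label.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    labels = mask.labels
    if radius_px == 0 or labels.max() == 0:
        return LabelMask(labels.copy(), mask.field_id)
    distance, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    expanded = labels[ir, ic]
    expanded[distance > radius_px] = 0
    return LabelMask(expanded.astype(np.int32), mask.field_id)
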
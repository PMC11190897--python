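"""Immunocytochemistry cell counting on two-channel 8-bit micrographs.

Each channel (neuron marker / nuclear stain) is binarized with the
Kittler-Illingworth minimum-error threshold, touching objects are split by
distance-transform watershed, small components are discarded, and the
neuron fraction is the ratio of marker-positive to nuclear-positive
object counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "SegmentationResult",
    "min_error_threshold",
    "segment_objects",
    "count_channel",
    "neuron_fraction",
]


@dataclass
class SegmentationResult:
    threshold: int
    labels: np.ndarray
    count: int
    areas: np.ndarray


def min_error_threshold(img: np.ndarray) -> int:
    """Kittler-Illingworth minimum-error threshold of an 8-bit image.

    Models the histogram as two Gaussian classes split at t and minimizes
    the classification-error criterion
    J(t) = 1 + 2[P1 ln s1 + P2 ln s2] - 2[P1 ln P1 + P2 ln P2]
    over t in [0, 255]; ties break toward the lower t. Thresholds where
    either class is empty (or has zero variance) are skipped.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("expected 8-bit intensities in [0, 255]")
        img = img.astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    if (hist > 0).sum() < 2:
        raise ValueError("constant image: no threshold exists")

    levels = np.arange(256, dtype=float)
    w = hist / hist.sum()
    # cumulative moments for all candidate thresholds at once
    P1 = np.cumsum(w)
    m1 = np.cumsum(w * levels)
    s1 = np.cumsum(w * levels**2)
    P2 = 1.0 - P1
    mu1 = np.where(P1 > 0, m1 / np.maximum(P1, 1e-300), 0.0)
    mu2 = np.where(P2 > 0, (m1[-1] - m1) / np.maximum(P2, 1e-300), 0.0)
    var1 = np.where(P1 > 0, s1 / np.maximum(P1, 1e-300) - mu1**2, 0.0)
    var2 = np.where(P2 > 0, (s1[-1] - s1) / np.maximum(P2, 1e-300) - mu2**2, 0.0)

    valid = (P1 > 0) & (P2 > 0) & (var1 > 0) & (var2 > 0)
    j = np.full(256, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        j[valid] = 1.0 + 2.0 * (
            P1[valid] * 0.5 * np.log(var1[valid]) + P2[valid] * 0.5 * np.log(var2[valid])
        ) - 2.0 * (P1[valid] * np.log(P1[valid]) + P2[valid] * np.log(P2[valid]))
    if not np.isfinite(j).any():
        # two spikes with zero spread: any level between them separates
        nz = np.flatnonzero(hist)
        return int(nz[0] + (nz[-1] - nz[0]) // 2)
    # empty histogram gaps give flat J plateaus (identical class split), so
    # break ties toward the lowest level within numerical tolerance
    jmin = j.min()
    return int(np.flatnonzero(j <= jmin + 1e-9 * max(1.0, abs(jmin)))[0])


def segment_objects(
    binary: np.ndarray, min_area_px: int = 30, min_distance_px: int = 7
) -> SegmentationResult:
    """Distance-transform watershed segmentation of a binary mask.

    Markers are local maxima of the Euclidean distance transform at least
    ``min_distance_px`` apart, so touching near-convex objects are split
    while lone objects stay whole. Components smaller than ``min_area_px``
    are discarded. An empty mask gives count 0.
    """
    binary = np.asarray(binary).astype(bool)
    if not binary.any():
        return SegmentationResult(0, np.zeros_like(binary, dtype=np.int32), 0, np.array([]))
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist, min_distance=min_distance_px, labels=binary, exclude_border=False
    )
    markers = np.zeros_like(binary, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels = sk_label(binary)
    else:
        labels = watershed(-dist, markers=markers, mask=binary)
    props = regionprops(labels)
    keep = [p for p in props if p.area >= min_area_px]
    out = np.zeros_like(labels)
    areas = []
    for new_id, p in enumerate(keep, start=1):
        out[labels == p.label] = new_id
        areas.append(p.area)
    return SegmentationResult(0, out, len(keep), np.asarray(areas, dtype=float))


def count_channel(
    img: np.ndarray,
    min_area_px: int = 30,
    min_distance_px: int = 7,
    threshold: int | None = None,
) -> SegmentationResult:
    """Threshold (minimum-error unless overridden) then segment and count."""
    t = min_error_threshold(img) if threshold is None else int(threshold)
    seg = segment_objects(img > t, min_area_px=min_area_px, min_distance_px=min_distance_px)
    seg.threshold = t
    return seg


def neuron_fraction(marker_seg: SegmentationResult, nuclear_seg: SegmentationResult) -> dict:
    """Marker-positive count / nuclear-positive count.

    Nuclear stain marks every cell (neurons and satellite cells), so the
    ratio is the neuron fraction of the culture. A ratio above 1 is
    reported with a clipped flag rather than an error.
    """
    if nuclear_seg.count == 0:
        raise ValueError("no nuclear objects: ratio undefined")
    ratio = marker_seg.count / nuclear_seg.count
    return {
        "n_neurons": marker_seg.count,
        "n_nuclei": nuclear_seg.count,
        "ratio": ratio,
        "clipped": ratio > 1.0,
    }
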
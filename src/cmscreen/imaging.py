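"""Image quantification: stitching, nucleus segmentation, marker scoring,
and nuclei-per-cell assignment.

The pipeline mirrors a standard high-content workflow: tiles are stitched
by known stage position (no registration), the stitched nuclei channel is
smoothed, thresholded and labelled, oversized components are declumped by
intensity-seeded watershed, and detections are reported in physical
units. Binucleation is scored by dropping nucleus centroids onto a
cell-boundary label image and counting nuclei per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "StitchError",
    "SegmentationParams",
    "NucleusDetection",
    "stitch_tiles",
    "segment_nuclei",
    "count_nuclei",
    "marker_positive_fraction",
    "assign_nuclei_to_cells",
    "binucleation_proportion",
]


class StitchError(ValueError):
    """Raised when the tile set does not cover the stated grid."""


@dataclass(frozen=True)
class SegmentationParams:
    """Nucleus segmentation tunables, all in physical units.

    threshold_method is "otsu" (global Otsu on the smoothed image, floored
    at a robust background bound) or "fixed" (use threshold_value). A
    connected component is split by seeded watershed only when its area
    exceeds ``split_area_factor`` times the median component area, with
    seeds at smoothed-intensity maxima; ``split_min_distance_um`` is the
    closest nucleus-center separation the splitter is asked to resolve.
    Detections outside [min_area_um2, max_area_um2] are discarded;
    edge-touching detections are kept unless ``exclude_edges``.
    """

    pixel_size_um: float = 2.0
    smoothing_sigma_um: float = 1.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area_um2: float = 15.0
    max_area_um2: float = 500.0
    split_min_distance_um: float = 8.0
    split_area_factor: float = 1.5
    exclude_edges: bool = False

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area must be smaller than max_area")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")


@dataclass
class NucleusDetection:
    """One detected nucleus, in physical units (x right, y down, origin at
    the image corner; a pixel's center is at (index + 0.5) * pixel size)."""

    x_um: float
    y_um: float
    area_um2: float
    mean_intensity: float
    mean_marker_intensity: float | None = None


def stitch_tiles(
    tiles: Mapping[tuple[int, int], np.ndarray], overlap_px: int = 0
) -> np.ndarray:
    """Mosaic tiles by grid position; overlapping strips are averaged.

    ``tiles`` maps (row, col) grid positions to equally-shaped 2-D arrays.
    Output dimensions are the grid extent minus the overlaps. A missing
    grid position raises :class:`StitchError` naming it.
    """
    if not tiles:
        raise StitchError("no tiles given")
    keys = list(tiles.keys())
    n_rows = max(k[0] for k in keys) + 1
    n_cols = max(k[1] for k in keys) + 1
    shapes = {np.asarray(t).shape for t in tiles.values()}
    if len(shapes) != 1:
        raise StitchError(f"tiles differ in shape: {sorted(shapes)}")
    th, tw = shapes.pop()
    if overlap_px < 0 or (n_rows > 1 and overlap_px >= th) or (n_cols > 1 and overlap_px >= tw):
        raise StitchError("overlap must be in [0, tile size)")
    for r in range(n_rows):
        for c in range(n_cols):
            if (r, c) not in tiles:
                raise StitchError(f"missing tile at grid position ({r}, {c})")
    H = n_rows * th - (n_rows - 1) * overlap_px
    W = n_cols * tw - (n_cols - 1) * overlap_px
    acc = np.zeros((H, W), dtype=float)
    weight = np.zeros((H, W), dtype=float)
    step_r, step_c = th - overlap_px, tw - overlap_px
    for (r, c), tile in tiles.items():
        i0, j0 = r * step_r, c * step_c
        acc[i0 : i0 + th, j0 : j0 + tw] += np.asarray(tile, dtype=float)
        weight[i0 : i0 + th, j0 : j0 + tw] += 1.0
    return acc / weight


def _split_component(
    mask: np.ndarray, intensity: np.ndarray, min_distance_px: int
) -> np.ndarray:
    """Watershed-split one component mask; returns an int label array.

    Seeds are local maxima of the smoothed intensity inside the mask
    (intensity declumping resolves closer pairs than the distance
    transform can); the exclusion radius between seeds is half the
    requested split distance so pairs just under it still yield two seeds.
    """
    peaks = peak_local_max(
        intensity,
        min_distance=max(min_distance_px // 2 - 1, 1),
        labels=mask,
        exclude_border=False,
    )
    if len(peaks) < 2:
        return mask.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    return watershed(-intensity, markers, mask=mask)


def segment_nuclei(
    image: np.ndarray, params: SegmentationParams
) -> list[NucleusDetection]:
    """Detect nuclei in a single-channel stitched image.

    Gaussian smoothing -> global threshold -> connected components ->
    watershed splitting of oversized components -> area filter. An image
    entirely below threshold yields an empty list, never an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    px = params.pixel_size_um
    px_area = px * px
    sigma_px = params.smoothing_sigma_um / px
    sm = ndi.gaussian_filter(img, sigma_px) if sigma_px > 0 else img
    if params.threshold_method == "fixed":
        thr = float(params.threshold_value)
    else:
        if np.ptp(sm) == 0:
            return []
        # Otsu splits the background noise when an image has no nuclei
        # (dead wells); floor the threshold at a robust background bound.
        med = float(np.median(sm))
        mad = float(np.median(np.abs(sm - med)))
        floor = med + 5.0 * 1.4826 * mad
        thr = max(float(threshold_otsu(sm)), floor)
    mask = sm > thr
    if not mask.any():
        return []

    lbl, n = ndi.label(mask)
    if n == 0:
        return []
    areas = ndi.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    plausible = areas[areas * px_area >= params.min_area_um2]
    median_area = float(np.median(plausible)) if plausible.size else float(np.median(areas))
    split_thr = params.split_area_factor * median_area
    min_dist_px = int(round(params.split_min_distance_um / px))

    out = np.zeros_like(lbl)
    next_label = 1
    objects = ndi.find_objects(lbl)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = lbl[sl] == i
        if areas[i - 1] > split_thr:
            sub = _split_component(comp, sm[sl], min_dist_px)
        else:
            sub = comp.astype(np.int32)
        nsub = int(sub.max())
        region = out[sl]
        region[sub > 0] = sub[sub > 0] + (next_label - 1)
        next_label += nsub

    detections: list[NucleusDetection] = []
    h, w = img.shape
    for prop in regionprops(out, intensity_image=img):
        area_um2 = prop.area * px_area
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        if params.exclude_edges:
            r0, c0, r1, c1 = prop.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                continue
        cy, cx = prop.centroid_weighted
        detections.append(
            NucleusDetection(
                x_um=(cx + 0.5) * px,
                y_um=(cy + 0.5) * px,
                area_um2=float(area_um2),
                mean_intensity=float(prop.intensity_mean),
            )
        )
    return detections


def count_nuclei(detections: Sequence[NucleusDetection]) -> int:
    """Nuclei count of a well image: the number of detections."""
    return len(detections)


def marker_positive_fraction(
    detections: Sequence[NucleusDetection],
    marker_image: np.ndarray,
    threshold: float,
    pixel_size_um: float,
) -> float:
    """Fraction of nuclei whose mean marker intensity exceeds ``threshold``.

    The marker channel (same geometry as the nuclei image) is sampled in a
    disk of the detection's equivalent radius around each centroid; the
    sampled mean is stored on each detection's ``mean_marker_intensity``.
    Raises ValueError on an empty detection list (the fraction is
    undefined; the caller decides how to handle wells with no nuclei).
    """
    if not detections:
        raise ValueError("marker-positive fraction undefined for zero detections")
    marker = np.asarray(marker_image, dtype=float)
    h, w = marker.shape
    n_pos = 0
    for det in detections:
        r_px = max(math.sqrt(det.area_um2 / math.pi) / pixel_size_um, 1.0)
        ci = det.y_um / pixel_size_um - 0.5
        cj = det.x_um / pixel_size_um - 0.5
        i0, i1 = max(int(ci - r_px), 0), min(int(ci + r_px) + 1, h)
        j0, j1 = max(int(cj - r_px), 0), min(int(cj + r_px) + 1, w)
        ii, jj = np.mgrid[i0:i1, j0:j1]
        disk = (ii - ci) ** 2 + (jj - cj) ** 2 <= r_px**2
        vals = marker[i0:i1, j0:j1][disk]
        mean = float(vals.mean()) if vals.size else 0.0
        det.mean_marker_intensity = mean
        if mean > threshold:
            n_pos += 1
    return n_pos / len(detections)


def assign_nuclei_to_cells(
    centroids_um: Iterable[tuple[float, float]],
    label_image: np.ndarray,
    pixel_size_um: float,
) -> tuple[dict[int, int], list[int]]:
    """Map nucleus centroids onto a cell-boundary label image.

    Each centroid takes the integer label of the pixel under it (0 =
    background). Returns (cell label -> nucleus count, indices of
    centroids that landed on background and are therefore unassigned).
    """
    lab = np.asarray(label_image)
    h, w = lab.shape
    counts: dict[int, int] = {}
    unassigned: list[int] = []
    for k, (x_um, y_um) in enumerate(centroids_um):
        i = min(max(int(y_um / pixel_size_um), 0), h - 1)
        j = min(max(int(x_um / pixel_size_um), 0), w - 1)
        val = int(lab[i, j])
        if val == 0:
            unassigned.append(k)
        else:
            counts[val] = counts.get(val, 0) + 1
    return counts, unassigned


def binucleation_proportion(cell_nuclei: Mapping[int, int]) -> float:
    """Fraction of assigned cells carrying two or more nuclei."""
    if not cell_nuclei:
        raise ValueError("binucleation proportion undefined for zero cells")
    n_bi = sum(1 for v in cell_nuclei.values() if v >= 2)
    return n_bi / len(cell_nuclei)
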
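"""Segmentation, object triage and single-cell morphometry.

The segmenter is deterministic and classical: nuclei from the DAPI channel
by smoothed Otsu thresholding, hole filling and a distance-transform
watershed split; cytoplasm grown from the nucleus seeds by a watershed on
the summed marker channels constrained to an Otsu foreground.  Connected
cell regions are triaged into single cells (one nucleus), clusters (two or
more nuclei) and artefacts (no nucleus, or failing size/solidity bounds).

Per cell the morphology vector holds the nucleus/cell ratios of area,
equivalent diameter, perimeter and major/minor axis, plus solidity,
orientation, eccentricity and convex area of both compartments, and
background-corrected per-channel mean intensities over each mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology, segmentation

from .scoring import background_mean

__all__ = [
    "SegmentationParams",
    "CellRecord",
    "ObjectTriage",
    "segment_nuclei",
    "segment_cells",
    "triage_objects",
    "extract_features",
    "extract_all_features",
    "aggregate_patient",
    "cell_crops",
]


@dataclass(frozen=True)
class SegmentationParams:
    smooth_sigma: float = 1.0
    min_nucleus_area: int = 30        # px^2
    min_peak_separation: int = 5      # px, watershed seed spacing
    min_cell_area: int = 80           # px^2, smaller objects are artefacts
    max_cell_area: int = 50000
    min_solidity: float = 0.5         # artefact bound


def segment_nuclei(dapi: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Nucleus label mask from a [0, 1] DAPI channel.

    Otsu threshold on the Gaussian-smoothed channel, hole filling, then a
    watershed split seeded at distance-transform peaks at least
    ``min_peak_separation`` apart; labels below ``min_nucleus_area`` are
    dropped.  A blank channel yields an empty mask.
    """
    smoothed = ndimage.gaussian_filter(np.asarray(dapi, dtype=float), params.smooth_sigma)
    if smoothed.max() - smoothed.min() < 1e-6:
        return np.zeros(smoothed.shape, dtype=np.int32)
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any() or fg.all():
        return np.zeros(smoothed.shape, dtype=np.int32)
    fg = ndimage.binary_fill_holes(fg)
    dist = ndimage.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        dist, min_distance=params.min_peak_separation, labels=fg,
        exclude_border=False)
    seeds = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        return np.zeros(fg.shape, dtype=np.int32)
    labels = segmentation.watershed(-dist, seeds, mask=fg)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < params.min_nucleus_area)
    labels[np.isin(labels, small[small > 0])] = 0
    return _relabel(labels)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Compact labels to 1..n preserving order."""
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def segment_cells(
    channels: np.ndarray, nucleus_labels: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Cell label mask grown from nucleus seeds.

    ``channels`` is the (n_channels, H, W) stack with DAPI first; the
    cytoplasm landscape is the smoothed sum of the marker channels (all
    but DAPI), its Otsu foreground bounds the watershed.  Every cell label
    contains its seed nucleus.
    """
    channels = np.asarray(channels, dtype=float)
    marker_sum = channels[1:].sum(axis=0) if channels.shape[0] > 1 else channels[0]
    smoothed = ndimage.gaussian_filter(marker_sum, params.smooth_sigma)
    if smoothed.max() - smoothed.min() < 1e-6:
        return np.zeros(smoothed.shape, dtype=np.int32)
    thr = filters.threshold_otsu(smoothed)
    fg = ndimage.binary_fill_holes(smoothed > thr)
    fg |= nucleus_labels > 0  # a cell region always covers its nucleus
    if not fg.any():
        return np.zeros(smoothed.shape, dtype=np.int32)
    labels = segmentation.watershed(-smoothed, nucleus_labels.astype(np.int32), mask=fg)
    # keep nucleus-free foreground (candidate artefacts) as extra labels
    orphan = fg & (labels == 0)
    if orphan.any():
        extra = measure.label(orphan)
        extra[extra > 0] += labels.max()
        labels = labels + extra
    return labels.astype(np.int32)


@dataclass(frozen=True)
class ObjectTriage:
    object_id: int
    kind: str  # cell | cluster | artefact


def triage_objects(
    cell_labels: np.ndarray, nucleus_labels: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> list[ObjectTriage]:
    """Categorise each connected cell region.

    A region is a cluster when it contains >= 2 nuclei, an artefact when
    it contains none or fails the size/solidity bounds, otherwise a cell.
    Touching regions that share a connected component are grouped: their
    nucleus count is counted over the component.
    """
    out = []
    comp = measure.label(cell_labels > 0)
    # map every cell label to its connected component
    comp_of_label: dict[int, int] = {}
    for region in measure.regionprops(cell_labels):
        r, c = region.coords[0]
        comp_of_label[region.label] = comp[r, c]
    # nuclei per component
    nuc_comp_counts: dict[int, int] = {}
    for region in measure.regionprops(nucleus_labels):
        r, c = region.coords[0]
        cid = comp[r, c]
        nuc_comp_counts[cid] = nuc_comp_counts.get(cid, 0) + 1

    for region in measure.regionprops(cell_labels):
        cid = comp_of_label[region.label]
        n_nuclei = nuc_comp_counts.get(cid, 0)
        if n_nuclei == 0:
            kind = "artefact"
        elif n_nuclei >= 2:
            kind = "cluster"
        else:
            kind = "cell"
            if (region.area < params.min_cell_area
                    or region.area > params.max_cell_area
                    or region.solidity < params.min_solidity):
                kind = "artefact"
        out.append(ObjectTriage(object_id=int(region.label), kind=kind))
    return out


@dataclass
class CellRecord:
    """One segmented cell's morphology + intensity feature vector."""

    object_id: int
    morph: dict[str, float]
    intensity: dict[str, float]
    atypia_prob: float = float("nan")
    valid: bool = True

    def as_row(self) -> dict[str, float]:
        row = {"object_id": self.object_id, "valid": self.valid,
               "atypia_prob": self.atypia_prob}
        row.update(self.morph)
        row.update(self.intensity)
        return row


_MIN_VALID_AREA = 4  # px^2; below this second moments are meaningless


def extract_features(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, channels: np.ndarray,
    channel_names: tuple[str, ...], object_id: int = 0,
    backgrounds: dict[str, float] | None = None,
) -> CellRecord:
    """Morphology and intensity features for one nucleus-in-cell pair.

    Ratios are nucleus/cell for area, equivalent diameter, perimeter and
    major/minor axis length; solidity, orientation, eccentricity and
    convex area are reported for both compartments; intensities are
    background-corrected channel means over each mask.
    """
    cell_mask = cell_mask.astype(bool)
    nucleus_mask = nucleus_mask.astype(bool) & cell_mask
    if cell_mask.sum() < _MIN_VALID_AREA or nucleus_mask.sum() < _MIN_VALID_AREA:
        return CellRecord(object_id=object_id, morph={}, intensity={}, valid=False)
    cprops = measure.regionprops(cell_mask.astype(np.uint8))[0]
    nprops = measure.regionprops(nucleus_mask.astype(np.uint8))[0]

    def safe_ratio(num, den):
        return float(num) / float(den) if den > 0 else float("nan")

    morph = {
        "nc_area_ratio": safe_ratio(nprops.area, cprops.area),
        "diameter_ratio": safe_ratio(nprops.equivalent_diameter_area,
                                     cprops.equivalent_diameter_area),
        "perimeter_ratio": safe_ratio(nprops.perimeter, cprops.perimeter),
        "major_axis_ratio": safe_ratio(nprops.axis_major_length,
                                       cprops.axis_major_length),
        "minor_axis_ratio": safe_ratio(nprops.axis_minor_length,
                                       cprops.axis_minor_length),
        "solidity_cell": float(cprops.solidity),
        "solidity_nucleus": float(nprops.solidity),
        "orientation_cell": float(cprops.orientation),
        "orientation_nucleus": float(nprops.orientation),
        "eccentricity_cell": float(cprops.eccentricity),
        "eccentricity_nucleus": float(nprops.eccentricity),
        "convex_area_cell": float(cprops.area_convex),
        "convex_area_nucleus": float(nprops.area_convex),
    }
    backgrounds = backgrounds or {}
    intensity = {}
    for ci, name in enumerate(channel_names):
        bg = backgrounds.get(name, 0.0)
        intensity[f"{name}_cell_mean"] = max(
            0.0, float(channels[ci][cell_mask].mean()) - bg)
        intensity[f"{name}_nucleus_mean"] = max(
            0.0, float(channels[ci][nucleus_mask].mean()) - bg)
    return CellRecord(object_id=object_id, morph=morph, intensity=intensity)


def extract_all_features(
    channels: np.ndarray, cell_labels: np.ndarray, nucleus_labels: np.ndarray,
    channel_names: tuple[str, ...],
    triage: list[ObjectTriage] | None = None,
) -> pd.DataFrame:
    """CellRecord table for every triaged single cell in an image."""
    if triage is None:
        triage = triage_objects(cell_labels, nucleus_labels)
    kinds = {t.object_id: t.kind for t in triage}
    backgrounds = {name: background_mean(channels[ci], cell_labels)
                   for ci, name in enumerate(channel_names)}
    rows = []
    for region in measure.regionprops(cell_labels):
        if kinds.get(region.label) != "cell":
            continue
        cmask = cell_labels == region.label
        nmask = (nucleus_labels > 0) & cmask
        rec = extract_features(cmask, nmask, channels, channel_names,
                               object_id=int(region.label),
                               backgrounds=backgrounds)
        rows.append(rec.as_row())
    return pd.DataFrame(rows)


def aggregate_patient(
    cells: pd.DataFrame, clinical: dict | None = None,
    atypia_threshold: float = 0.5,
) -> dict[str, float]:
    """Patient-level statistical aggregates over a CellRecord table.

    Per numeric feature: average, maximum and population SD.  Adds the
    fraction of cells with atypia probability above ``atypia_threshold``
    and the mean atypia probability, then passes clinical fields through.
    """
    cells = cells[cells.get("valid", pd.Series(True, index=cells.index)).astype(bool)]
    if len(cells) == 0:
        raise ValueError("no valid cells to aggregate")
    out: dict[str, float] = {}
    skip = {"object_id", "valid", "atypia_prob"}
    for col in cells.columns:
        if col in skip or not np.issubdtype(cells[col].dtype, np.number):
            continue
        v = cells[col].to_numpy(dtype=float)
        out[f"{col}_avg"] = float(np.mean(v))
        out[f"{col}_max"] = float(np.max(v))
        out[f"{col}_sd"] = float(np.std(v))  # population SD
    probs = cells["atypia_prob"].to_numpy(dtype=float)
    if np.isfinite(probs).all():
        out["atypical_ratio"] = float(np.mean(probs > atypia_threshold))
        out["mean_atypia_prob"] = float(np.mean(probs))
    if clinical:
        out.update(clinical)
    return out


def evaluate_segmentation(
    truth_cell_labels: np.ndarray, truth_table: pd.DataFrame,
    cell_labels: np.ndarray, nucleus_labels: np.ndarray,
    iou_threshold: float = 0.8,
) -> dict[str, float]:
    """Score a segmentation against simulator ground truth.

    A true cell counts as detected when some predicted region overlaps it
    with IoU >= ``iou_threshold``.  For detected cells the recovered
    nucleus/cell area ratio is compared to the truth table's value.
    Returns detection_rate, mean IoU over detected cells and the N/C-ratio
    mean absolute error.
    """
    truth_cells = truth_table[truth_table["type"] == "cell"]
    ious, nc_errors = [], []
    detected = 0
    for _, row in truth_cells.iterrows():
        tmask = truth_cell_labels == row["object_id"]
        inside = cell_labels[tmask]
        labs, counts = np.unique(inside[inside > 0], return_counts=True)
        if len(labs) == 0:
            continue
        lab = labs[np.argmax(counts)]
        pmask = cell_labels == lab
        iou = (tmask & pmask).sum() / (tmask | pmask).sum()
        if iou < iou_threshold:
            continue
        detected += 1
        ious.append(iou)
        nc = ((nucleus_labels > 0) & pmask).sum() / pmask.sum()
        nc_errors.append(abs(nc - row["nc_ratio"]))
    n = len(truth_cells)
    return {
        "n_true_cells": float(n),
        "detection_rate": detected / n if n else float("nan"),
        "mean_iou": float(np.mean(ious)) if ious else float("nan"),
        "nc_ratio_mae": float(np.mean(nc_errors)) if nc_errors else float("nan"),
    }


def cell_crops(
    channels: np.ndarray, cell_labels: np.ndarray,
    triage: list[ObjectTriage], size: int = 64, median_filter: int = 3,
) -> tuple[np.ndarray, list[int]]:
    """Median-filtered square crops centred on each single cell.

    Returns (crops of shape (n, n_channels, size, size), object ids).
    Cells whose bounding box exceeds the crop are centre-cropped.
    """
    n_ch, h, w = channels.shape
    filtered = np.stack([ndimage.median_filter(channels[ci], size=median_filter)
                         for ci in range(n_ch)])
    crops, ids = [], []
    for t in triage:
        if t.kind != "cell":
            continue
        ys, xs = np.nonzero(cell_labels == t.object_id)
        cy, cx = int(ys.mean()), int(xs.mean())
        half = size // 2
        y0, x0 = cy - half, cx - half
        crop = np.zeros((n_ch, size, size), dtype=float)
        sy0, sy1 = max(0, y0), min(h, y0 + size)
        sx0, sx1 = max(0, x0), min(w, x0 + size)
        crop[:, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = filtered[:, sy0:sy1, sx0:sx1]
        crops.append(crop)
        ids.append(t.object_id)
    if not crops:
        return np.zeros((0, n_ch, size, size)), []
    return np.stack(crops), ids
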
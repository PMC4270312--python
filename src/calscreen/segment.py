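"""Nuclei detection, seeded cell-boundary growing, edge exclusion and
field-level intensity quantification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

logger = logging.getLogger(__name__)

__all__ = [
    "LabelImage",
    "CellRecord",
    "detect_nuclei",
    "grow_cell_boundaries",
    "exclude_edge_cells",
    "mean_field_intensity",
]


@dataclass
class LabelImage:
    """An integer label image (0 = background) with provenance."""

    labels: np.ndarray
    provenance: str  # "nuclei" | "cells"

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if self.provenance not in ("nuclei", "cells"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class CellRecord:
    """One segmented cell linked to its seeding nucleus."""

    cell_id: int
    nucleus_id: int
    area_px: int
    centroid: tuple[float, float]  # (row, col), 0-based
    edge_flag: bool = False


def _foreground_mask(frame: np.ndarray, threshold, sigma: float) -> np.ndarray:
    smoothed = gaussian(frame.astype(float), sigma=sigma, preserve_range=True)
    if isinstance(threshold, (int, float)):
        thr = float(threshold)
    elif threshold == "otsu":
        if smoothed.max() == smoothed.min():
            return np.zeros(frame.shape, dtype=bool)
        thr = threshold_otsu(smoothed)
    else:
        raise ValueError(f"unknown threshold method {threshold!r}")
    return smoothed > thr


def detect_nuclei(
    nuclear_frame: np.ndarray,
    min_area: int = 30,
    threshold: str | float = "otsu",
    sigma: float = 2.0,
    min_peak_distance: int = 5,
) -> LabelImage:
    """Detect nuclei in the far-red channel.

    Thresholds the smoothed frame (Otsu by default), splits fused blobs with
    a distance-transform watershed, and discards regions below ``min_area``.
    An all-zero frame yields zero labels.
    """
    frame = np.asarray(nuclear_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("nuclear frame must be 2-D")
    if np.any(frame < 0):
        raise ValueError("nuclear frame must be nonnegative")
    mask = _foreground_mask(frame, threshold, sigma)
    if not mask.any():
        return LabelImage(np.zeros(frame.shape, dtype=np.int32), "nuclei")

    distance = ndi.distance_transform_edt(mask)
    peak_coords = peak_local_max(
        distance,
        min_distance=min_peak_distance,
        labels=ndi.label(mask)[0],
        exclude_border=False,
    )
    markers = np.zeros(frame.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peak_coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # tiny blobs with no distinct peak
        markers, _ = ndi.label(mask)
    labels = watershed(-distance, markers, mask=mask)

    # drop regions below the minimum area, then relabel contiguously
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return LabelImage(labels.astype(np.int32), "nuclei")


def grow_cell_boundaries(
    cyto_frame: np.ndarray,
    nuclei: LabelImage,
    threshold: str | float = "otsu",
    sigma: float = 2.0,
) -> tuple[LabelImage, list[CellRecord]]:
    """Grow cell boundaries from nucleus seeds over the cytoplasmic signal.

    A watershed seeded by the nucleus labels is restricted to the
    thresholded cytoplasmic foreground, so the resulting cells partition the
    foreground and each contains exactly one nucleus.  Nuclei falling
    entirely outside the foreground are dropped with a warning.
    """
    if nuclei.provenance != "nuclei":
        raise ValueError("seed image must have provenance 'nuclei'")
    if nuclei.n_labels == 0:
        raise ValueError("no nuclei to seed from")
    frame = np.asarray(cyto_frame, dtype=float)
    fg = _foreground_mask(frame, threshold, sigma)
    fg |= nuclei.labels > 0  # nuclei always belong to their cell

    seeds = nuclei.labels.copy()
    kept = []
    for nid in range(1, nuclei.n_labels + 1):
        inside = (seeds == nid) & fg
        if not inside.any():
            logger.warning("nucleus %d lies outside the cytoplasm mask; dropped", nid)
            seeds[seeds == nid] = 0
        else:
            kept.append(nid)

    distance = ndi.distance_transform_edt(fg)
    labels = watershed(-distance, seeds, mask=fg)
    cells = LabelImage(labels.astype(np.int32), "cells")

    records = []
    for prop in regionprops(cells.labels):
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                nucleus_id=int(prop.label),
                area_px=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    return cells, records


def exclude_edge_cells(
    cells: list[CellRecord], labels: LabelImage
) -> list[CellRecord]:
    """Drop every cell with at least one pixel on the image border.

    Removed records get ``edge_flag=True``; the returned list contains only
    interior cells.
    """
    lab = labels.labels
    border = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    edge_ids = set(np.unique(border[border > 0]).tolist())
    retained = []
    for rec in cells:
        if rec.cell_id in edge_ids:
            rec.edge_flag = True
        else:
            retained.append(rec)
    if cells and not retained:
        logger.warning("all %d cells touch the image border", len(cells))
    return retained


def mean_field_intensity(
    frame: np.ndarray, background: float | None = None
) -> float:
    """Mean pixel intensity of a field, optionally background-subtracted.

    ``background`` is a percentile in [0, 100); the corresponding intensity
    is subtracted before averaging.  Default is the plain mean.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if background is None:
        return float(frame.mean())
    if not 0 <= background < 100:
        raise ValueError("background percentile must be in [0, 100)")
    return float((frame - np.percentile(frame, background)).mean())
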
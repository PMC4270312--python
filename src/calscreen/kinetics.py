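"""Per-cell ratio traces, dF/F0 normalization, peak extraction and
well-level summaries.

The normalization is dff(t) = (F(t) - F0) / F0 with F0 the mean ratio over
all frames preceding the stimulus dispense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionSchedule
from .segment import CellRecord
from .synth import ImageStackSet

__all__ = [
    "CalciumTrace",
    "WellSummary",
    "TraceError",
    "extract_ratio_trace",
    "extract_all_traces",
    "compute_dff",
    "peak_amplitude",
    "classify_responsive",
    "summarize_well",
]

#: default responder threshold on peak dF/F0 (boundary inclusive)
DEFAULT_RESPONDER_THRESHOLD = 0.1


class TraceError(ValueError):
    """Raised when a cell's trace cannot be quantified."""


@dataclass
class CalciumTrace:
    """One cell's ratio trace with its normalized series and peak."""

    cell_id: int
    ratio: np.ndarray
    f0: float
    dff: np.ndarray
    peak_amplitude: float
    responsive: bool | None = None


@dataclass
class WellSummary:
    """Responder-filtered readout of one well."""

    address: str
    n_cells: int
    n_responsive: int
    mean_peak: float  # nan when no responsive cells
    sd_peak: float  # nan when < 2 responsive cells
    valid: bool = True


def extract_ratio_trace(
    stack: ImageStackSet, cell: CellRecord, labels: np.ndarray, erode_px: int = 2
) -> np.ndarray:
    """Acceptor/donor ratio of one cell at every frame.

    ratio(t) = mean(YFP pixels of the cell) / mean(CFP pixels of the cell).
    The mask is eroded by ``erode_px`` to keep boundary/background pixels
    from diluting the means (skipped if erosion would empty the cell).
    """
    mask = labels == cell.cell_id
    if not mask.any():
        raise TraceError(f"cell {cell.cell_id} has no pixels in the label image")
    if erode_px > 0:
        from scipy.ndimage import binary_erosion

        eroded = binary_erosion(mask, iterations=erode_px)
        if eroded.any():
            mask = eroded
    cfp_means = stack.cfp[:, mask].mean(axis=1)
    yfp_means = stack.yfp[:, mask].mean(axis=1)
    if np.any(cfp_means <= 0):
        raise TraceError(
            f"cell {cell.cell_id}: nonpositive donor signal at frame "
            f"{int(np.argmax(cfp_means <= 0))}"
        )
    return yfp_means / cfp_means


def compute_dff(
    ratio: np.ndarray, schedule: AcquisitionSchedule, cell_id: int = 0
) -> CalciumTrace:
    """Normalize a ratio series to its pre-stimulus baseline.

    F0 is the mean over all frames before the dispense index.
    """
    ratio = np.asarray(ratio, dtype=float)
    if ratio.size != schedule.n_frames:
        raise ValueError("ratio series length must match the schedule")
    f0 = float(ratio[schedule.pre_indices].mean())
    if f0 <= 0:
        raise TraceError(f"cell {cell_id}: nonpositive baseline F0={f0}")
    dff = (ratio - f0) / f0
    return CalciumTrace(
        cell_id=cell_id,
        ratio=ratio,
        f0=f0,
        dff=dff,
        peak_amplitude=float(dff[schedule.post_indices].max()),
    )


def peak_amplitude(trace: CalciumTrace, schedule: AcquisitionSchedule | None = None) -> float:
    """Maximum dF/F0 over the frames at/after the dispense frame."""
    if schedule is not None:
        return float(trace.dff[schedule.post_indices].max())
    return trace.peak_amplitude


def classify_responsive(
    peak: float, threshold: float = DEFAULT_RESPONDER_THRESHOLD
) -> bool:
    """A cell responds iff its peak dF/F0 reaches the threshold (>=)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return peak >= threshold


def summarize_well(
    traces: list[CalciumTrace],
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
    address: str = "",
) -> WellSummary:
    """Mean and sd of peak amplitude over the responsive cells of a well.

    A well with zero responsive cells is flagged invalid (excluded from
    downstream normalization).
    """
    if not traces:
        raise ValueError("cannot summarize a well without traces")
    for tr in traces:
        tr.responsive = classify_responsive(tr.peak_amplitude, threshold)
    peaks = np.array([tr.peak_amplitude for tr in traces if tr.responsive])
    n_resp = int(peaks.size)
    return WellSummary(
        address=address,
        n_cells=len(traces),
        n_responsive=n_resp,
        mean_peak=float(peaks.mean()) if n_resp else float("nan"),
        sd_peak=float(peaks.std(ddof=1)) if n_resp >= 2 else float("nan"),
        valid=n_resp >= 1,
    )


def extract_all_traces(
    stack: ImageStackSet,
    cells: list[CellRecord],
    labels: np.ndarray,
) -> list[CalciumTrace]:
    """Extract and normalize traces for every cell; unquantifiable cells are
    skipped."""
    out = []
    for cell in cells:
        try:
            ratio = extract_ratio_trace(stack, cell, labels)
            out.append(compute_dff(ratio, stack.schedule, cell_id=cell.cell_id))
        except TraceError:
            continue
    return out
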
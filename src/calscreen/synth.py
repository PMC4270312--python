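"""Ground-truthed synthetic inputs for every pipeline stage.

Generates per-well time-lapse image stacks of ratiometric sensor cells with
a far-red nuclear channel, whole plates of such stacks, dose-response tables
and immunoassay plates.  Every generator is a pure function of its
parameters and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .core import AcquisitionSchedule, PlateLayout, WellRole

__all__ = [
    "TransientParams",
    "FieldSpec",
    "CellTruth",
    "GroundTruth",
    "ImageStackSet",
    "simulate_transient",
    "render_field",
    "simulate_screen_plate",
    "simulate_plate_cell_peaks",
    "simulate_dose_table",
    "simulate_elisa_plate",
    "DEFAULT_CONTROL_SCALINGS",
]

#: Peak-scaling presets for the positive-control wells (configurable).
DEFAULT_CONTROL_SCALINGS: dict[str, float] = {
    "TP": 0.15,
    "CPA": 0.2,
    "TMB-8": 0.4,
    "Bepridil": 0.5,
}


@dataclass(frozen=True)
class TransientParams:
    """Parameters of one simulated stimulus-evoked ratio transient."""

    baseline_ratio: float = 1.0
    peak_dff: float = 0.8
    rise_tau: float = 0.8
    decay_tau: float = 4.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be > 0")
        if self.peak_dff < 0:
            raise ValueError("peak_dff must be >= 0")
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and intensity parameters of one rendered imaging field."""

    shape: tuple[int, int] = (96, 96)
    n_cells: int = 12
    cell_radius: tuple[float, float] = (6.0, 8.5)
    nucleus_radius: tuple[float, float] = (3.5, 4.8)
    fraction_nonresponsive: float = 0.0
    fraction_edge: float = 0.0
    background: float = 20.0
    background_noise: float = 0.0
    cell_intensity: float = 400.0
    nuclear_intensity: float = 180.0
    pixel_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.nucleus_radius[1] >= self.cell_radius[0]:
            raise ValueError("nucleus radius must be below cell radius")
        for f in (self.fraction_nonresponsive, self.fraction_edge):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class CellTruth:
    """Ground-truth record for one rendered cell."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    radius: float
    nucleus_center: tuple[float, float]
    nucleus_radius: float
    peak_dff: float
    responsive: bool
    edge: bool


@dataclass
class GroundTruth:
    """Ground truth for a rendered field (and, plate-wide, per-well effects)."""

    cells: list[CellTruth] = field(default_factory=list)
    cell_labels: np.ndarray | None = None
    nucleus_labels: np.ndarray | None = None
    well_scaling: float = 1.0
    genotype_factor: float = 1.0
    true_peak_dff: float | None = None


@dataclass
class ImageStackSet:
    """Per-well multi-channel time-lapse pixel data."""

    cfp: np.ndarray  # (T, H, W)
    yfp: np.ndarray  # (T, H, W)
    nuclear: np.ndarray  # (T, H, W)
    schedule: AcquisitionSchedule
    well: str = ""
    plate_id: str = ""

    def __post_init__(self) -> None:
        if not (self.cfp.shape == self.yfp.shape == self.nuclear.shape):
            raise ValueError("channel stacks must share a shape")
        if self.cfp.shape[0] != self.schedule.n_frames:
            raise ValueError("stack frame count does not match schedule")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.cfp.shape[1:]

    def write_tiffs(self, directory: str | Path) -> list[Path]:
        """Write one multi-page TIFF per channel:
        ``<plate>_<well>_<channel>.tif``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, stack in (("CFP", self.cfp), ("YFP", self.yfp), ("NUC", self.nuclear)):
            p = directory / f"{self.plate_id}_{self.well}_{name}.tif"
            tifffile.imwrite(p, stack.astype(np.float32))
            paths.append(p)
        return paths

    @classmethod
    def read_tiffs(
        cls,
        directory: str | Path,
        plate_id: str,
        well: str,
        schedule: AcquisitionSchedule,
    ) -> "ImageStackSet":
        directory = Path(directory)
        chans = {}
        for name in ("CFP", "YFP", "NUC"):
            chans[name] = tifffile.imread(directory / f"{plate_id}_{well}_{name}.tif")
        return cls(
            cfp=np.asarray(chans["CFP"], dtype=float),
            yfp=np.asarray(chans["YFP"], dtype=float),
            nuclear=np.asarray(chans["NUC"], dtype=float),
            schedule=schedule,
            well=well,
            plate_id=plate_id,
        )


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_transient(
    params: TransientParams,
    schedule: AcquisitionSchedule,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one ratio trace sampled on ``schedule``.

    Pre-stimulus frames sit at the baseline ratio R0.  Post-stimulus frames
    follow R0 * (1 + A * h(t)), where h is a saturating-rise/exponential-
    decay product rescaled so its noiseless maximum over the post-stimulus
    sample times is exactly 1 — the noiseless peak dF/F0 of the trace
    therefore equals ``peak_dff`` exactly.  Noise is multiplicative
    Gaussian with coefficient of variation ``noise_cv``.
    """
    rng = _rng(seed)
    t = np.asarray(schedule.timestamps, dtype=float)
    r = np.full(t.size, params.baseline_ratio, dtype=float)
    if params.peak_dff > 0:
        dt = t[schedule.post_indices] - t[schedule.dispense_index]
        h = (1.0 - np.exp(-dt / params.rise_tau)) * np.exp(-dt / params.decay_tau)
        hmax = h.max()
        if hmax <= 0:
            raise ValueError(
                "schedule has no post-stimulus frame after the dispense frame; "
                "cannot realize a nonzero peak"
            )
        r[schedule.post_indices] = params.baseline_ratio * (1.0 + params.peak_dff * h / hmax)
    if params.noise_cv > 0:
        r = r * (1.0 + rng.normal(0.0, params.noise_cv, size=r.size))
    return r


def _place_cells(
    spec: FieldSpec, rng: np.random.Generator, max_tries_per_cell: int = 400
) -> list[tuple[float, float, float]]:
    """Place non-overlapping disks; a requested fraction intersects the
    border."""
    h, w = spec.shape
    n_edge = int(round(spec.fraction_edge * spec.n_cells))
    placed: list[tuple[float, float, float]] = []
    for i in range(spec.n_cells):
        want_edge = i < n_edge
        r = rng.uniform(*spec.cell_radius)
        ok = False
        for _ in range(max_tries_per_cell):
            if want_edge:
                # center close enough to one border that the disk crosses it
                side = rng.integers(0, 4)
                off = rng.uniform(0.0, r - 1.5)
                if side == 0:
                    cy, cx = off, rng.uniform(r, w - r)
                elif side == 1:
                    cy, cx = h - 1 - off, rng.uniform(r, w - r)
                elif side == 2:
                    cy, cx = rng.uniform(r, h - r), off
                else:
                    cy, cx = rng.uniform(r, h - r), w - 1 - off
            else:
                # generous border margin so smoothing during segmentation
                # cannot push an interior cell onto the border
                cy = rng.uniform(r + 3.0, h - 1 - r - 3.0)
                cx = rng.uniform(r + 3.0, w - 1 - r - 3.0)
            if all(
                np.hypot(cy - py, cx - px) > r + pr + 2.0 for py, px, pr in placed
            ):
                placed.append((cy, cx, r))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{spec.shape} after bounded retries"
            )
    return placed


def render_field(
    spec: FieldSpec,
    traces: Sequence[np.ndarray],
    schedule: AcquisitionSchedule,
    seed: int | np.random.Generator = 0,
    true_peaks: Sequence[float] | None = None,
    responsive: Sequence[bool] | None = None,
    well: str = "",
    plate_id: str = "",
) -> tuple[ImageStackSet, GroundTruth]:
    """Render per-cell ratio traces into a three-channel image stack.

    Within each cell the donor+acceptor pixel sum is frame-constant while
    the acceptor/donor mean ratio equals the cell's trace value at every
    frame (ratiometric redistribution).  The nuclear channel is nonzero
    only inside nuclei.
    """
    if len(traces) != spec.n_cells:
        raise ValueError("traces count must equal n_cells")
    rng = _rng(seed)
    h, w = spec.shape
    nt = schedule.n_frames
    cfp = np.zeros((nt, h, w), dtype=float)
    yfp = np.zeros((nt, h, w), dtype=float)
    nuc = np.zeros((nt, h, w), dtype=float)

    placed = _place_cells(spec, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    truth = GroundTruth(cell_labels=cell_labels, nucleus_labels=nuc_labels)

    for i, (cy, cx, r) in enumerate(placed):
        cid = i + 1
        nr = rng.uniform(*spec.nucleus_radius)
        # nucleus jitter kept inside the cytoplasm
        max_off = max(r - nr - 1.5, 0.0)
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(0, max_off)
        ny, nx = cy + off * np.sin(ang), cx + off * np.cos(ang)
        cell_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        nuc_mask = (yy - ny) ** 2 + (xx - nx) ** 2 <= nr**2
        nuc_mask &= cell_mask
        cell_labels[cell_mask] = cid
        nuc_labels[nuc_mask] = cid

        ratio = np.asarray(traces[i], dtype=float)
        if ratio.size != nt:
            raise ValueError("trace length must equal schedule frame count")
        s = spec.cell_intensity
        cfp_vals = s / (1.0 + ratio)  # (T,)
        yfp_vals = s * ratio / (1.0 + ratio)
        cfp[:, cell_mask] = cfp_vals[:, None]
        yfp[:, cell_mask] = yfp_vals[:, None]
        nuc[:, nuc_mask] = spec.nuclear_intensity

        peak = float(true_peaks[i]) if true_peaks is not None else float("nan")
        resp = bool(responsive[i]) if responsive is not None else True
        # pixel-based edge flag, consistent with the downstream exclusion rule
        edge = bool(
            cell_mask[0, :].any()
            or cell_mask[-1, :].any()
            or cell_mask[:, 0].any()
            or cell_mask[:, -1].any()
        )
        truth.cells.append(
            CellTruth(
                cell_id=cid,
                center=(cy, cx),
                radius=r,
                nucleus_center=(ny, nx),
                nucleus_radius=nr,
                peak_dff=peak,
                responsive=resp,
                edge=edge,
            )
        )

    background_mask = cell_labels == 0
    cfp[:, background_mask] += spec.background
    yfp[:, background_mask] += spec.background
    if spec.pixel_noise_cv > 0:
        cfp *= 1.0 + rng.normal(0.0, spec.pixel_noise_cv, size=cfp.shape)
        yfp *= 1.0 + rng.normal(0.0, spec.pixel_noise_cv, size=yfp.shape)
    if spec.background_noise > 0:
        cfp += rng.normal(0.0, spec.background_noise, size=cfp.shape)
        yfp += rng.normal(0.0, spec.background_noise, size=yfp.shape)
        np.clip(cfp, 1e-6, None, out=cfp)
        np.clip(yfp, 0.0, None, out=yfp)

    stack = ImageStackSet(
        cfp=cfp, yfp=yfp, nuclear=nuc, schedule=schedule, well=well, plate_id=plate_id
    )
    return stack, truth


def _well_scaling(
    well_role: WellRole,
    compound_id: str | None,
    effects: Mapping[str, float],
    control_scalings: Mapping[str, float],
) -> float:
    if well_role in (WellRole.VEHICLE, WellRole.UNTREATED):
        return 1.0
    if well_role is WellRole.POSITIVE_CONTROL:
        if compound_id and compound_id in control_scalings:
            return control_scalings[compound_id]
        return 0.3
    if compound_id is None or compound_id not in effects:
        raise KeyError(f"no effect specified for test compound {compound_id!r}")
    return float(effects[compound_id])


def simulate_plate_cell_peaks(
    layout: PlateLayout,
    effects: Mapping[str, float],
    genotype_factor: float = 1.5,
    seed: int | np.random.Generator = 0,
    base_peak: float = 0.8,
    n_cells: int = 25,
    cell_peak_cv: float = 0.1,
    fraction_nonresponsive: float = 0.0,
    control_scalings: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Fast trace-free companion of :func:`simulate_screen_plate`.

    Returns, per well, the array of true per-cell peak dF/F0 values drawn
    with the same effect model (nonresponders have peak 0).  Used when the
    image-rendering stage is not under study.
    """
    rng = _rng(seed)
    controls = dict(DEFAULT_CONTROL_SCALINGS if control_scalings is None else control_scalings)
    out: dict[str, np.ndarray] = {}
    for wspec in layout.wells:
        scaling = _well_scaling(wspec.role, wspec.compound_id, effects, controls)
        a_well = base_peak * genotype_factor * scaling
        peaks = a_well * np.clip(
            1.0 + rng.normal(0.0, cell_peak_cv, size=n_cells), 0.0, None
        )
        if fraction_nonresponsive > 0:
            nonresp = rng.random(n_cells) < fraction_nonresponsive
            peaks[nonresp] = 0.0
        out[wspec.address] = peaks
    return out


def simulate_screen_plate(
    layout: PlateLayout,
    effects: Mapping[str, float],
    genotype_factor: float = 1.5,
    seed: int | np.random.Generator = 0,
    field_spec: FieldSpec | None = None,
    schedule: AcquisitionSchedule | None = None,
    base_peak: float = 0.8,
    cell_peak_cv: float = 0.1,
    trace_noise_cv: float = 0.0,
    baseline_ratio: float = 1.0,
    control_scalings: Mapping[str, float] | None = None,
) -> tuple[dict[str, ImageStackSet], dict[str, GroundTruth]]:
    """Simulate the image stacks of a whole screening plate.

    Vehicle and untreated wells carry peak scaling 1.0; test wells scale
    the base peak by ``effects[compound_id]``; positive-control wells use
    their preset scalings.  The well-level true peak is
    ``base_peak * genotype_factor * scaling``; individual cells jitter
    around it, and a configurable fraction does not respond at all.
    """
    from .core import default_schedule

    rng = _rng(seed)
    spec = field_spec or FieldSpec()
    sched = schedule or default_schedule()
    controls = dict(DEFAULT_CONTROL_SCALINGS if control_scalings is None else control_scalings)

    stacks: dict[str, ImageStackSet] = {}
    truths: dict[str, GroundTruth] = {}
    for wspec in layout.wells:
        scaling = _well_scaling(wspec.role, wspec.compound_id, effects, controls)
        a_well = base_peak * genotype_factor * scaling
        n = spec.n_cells
        responsive = rng.random(n) >= spec.fraction_nonresponsive
        peaks = np.where(
            responsive,
            a_well * np.clip(1.0 + rng.normal(0.0, cell_peak_cv, size=n), 0.0, None),
            0.0,
        )
        traces = [
            simulate_transient(
                TransientParams(
                    baseline_ratio=baseline_ratio,
                    peak_dff=float(p),
                    noise_cv=trace_noise_cv,
                ),
                sched,
                rng,
            )
            for p in peaks
        ]
        stack, truth = render_field(
            spec,
            traces,
            sched,
            seed=rng,
            true_peaks=peaks,
            responsive=responsive.tolist(),
            well=wspec.address,
            plate_id=layout.plate_id,
        )
        truth.well_scaling = scaling
        truth.genotype_factor = genotype_factor
        truth.true_peak_dff = a_well
        stacks[wspec.address] = stack
        truths[wspec.address] = truth
    return stacks, truths


def four_pl(c: np.ndarray | float, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic response at concentration ``c``."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


def simulate_dose_table(
    fpl,
    concentrations: Sequence[float],
    n_replicates: int = 8,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    compound_id: str = "compound",
):
    """Simulate a replicated dose-response table from a 4PL ground truth.

    ``fpl`` is any object with bottom/top/ec50/hill attributes
    (:class:`calscreen.pharm.FourPLParams`).  Concentrations are molar.
    """
    import pandas as pd

    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = _rng(seed)
    rows = []
    for c in conc:
        mu = float(four_pl(c, fpl.bottom, fpl.top, fpl.ec50, fpl.hill))
        eps = rng.normal(0.0, noise_cv, size=n_replicates) if noise_cv > 0 else np.zeros(n_replicates)
        for j in range(n_replicates):
            rows.append(
                {
                    "compound_id": compound_id,
                    "concentration": c,
                    "replicate": j + 1,
                    "response": mu * (1.0 + eps[j]),
                }
            )
    return pd.DataFrame(rows)


def simulate_elisa_plate(
    calib,
    standard_concs: Sequence[float],
    sample_concs: Mapping[str, float],
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 2,
):
    """Simulate an immunoassay plate: calibration standards plus samples.

    Signals are the 4PL calibration curve evaluated at the true
    concentration, with multiplicative Gaussian noise.  Standards span the
    quantifiable range and are labeled ``well_type == "standard"``.
    """
    import pandas as pd

    stds = np.asarray(standard_concs, dtype=float)
    if stds.size == 0:
        raise ValueError("need at least one calibration standard")
    if sample_concs:
        positives = [v for v in sample_concs.values() if v > 0]
        if positives and (min(positives) < stds.min() or max(positives) > stds.max()):
            raise ValueError("standards must span the sample concentration range")
    rng = _rng(seed)
    rows = []

    def signal_at(conc: float) -> float:
        mu = float(four_pl(conc, calib.bottom, calib.top, calib.ec50, calib.hill)) if conc > 0 else calib.bottom
        noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        return mu * (1.0 + noise)

    for c in stds:
        for j in range(n_replicates):
            rows.append(
                {
                    "well_type": "standard",
                    "sample_id": f"std_{c:.6g}",
                    "true_concentration": c,
                    "replicate": j + 1,
                    "signal": signal_at(c),
                }
            )
    for sid, c in sample_concs.items():
        for j in range(n_replicates):
            rows.append(
                {
                    "well_type": "sample",
                    "sample_id": sid,
                    "true_concentration": c,
                    "replicate": j + 1,
                    "signal": signal_at(c),
                }
            )
    return pd.DataFrame(rows)
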
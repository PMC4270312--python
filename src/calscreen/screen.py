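"""Vehicle normalization, replicate aggregation, hit calling, plate QC and
many-to-one statistics (one-way ANOVA with Dunnett's post hoc)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PlateLayout, WellRole
from .kinetics import WellSummary

logger = logging.getLogger(__name__)

__all__ = [
    "PlateResult",
    "StatsResult",
    "QCReport",
    "normalize_to_vehicle",
    "normalize_values",
    "aggregate_replicates",
    "call_hits",
    "qc_plate",
    "anova_dunnett",
    "star_annotation",
    "DEFAULT_HIT_THRESHOLD",
    "DEFAULT_MIN_RESPONSIVE_FRACTION",
]

DEFAULT_HIT_THRESHOLD = 0.9
#: wells with fewer responders than this fraction of cells are treated as
#: toxicity-interference and excluded from scoring
DEFAULT_MIN_RESPONSIVE_FRACTION = 0.2


@dataclass
class PlateResult:
    """Per-well vehicle-normalized readouts of one plate.

    ``wells`` columns: address, role, compound_id, replicate_group,
    n_cells, n_responsive, mean_peak, valid, normalized_value.
    """

    plate_id: str
    wells: pd.DataFrame
    vehicle_mean: float


@dataclass
class StatsResult:
    """One many-to-one comparison against the control group."""

    comparison: str
    f_statistic: float
    p_raw: float
    p_adjusted: float
    star: str


@dataclass
class QCReport:
    """Positive-control performance of one plate."""

    controls: pd.DataFrame  # compound_id, normalized_value, passed
    plate_pass: bool
    reason: str = ""


def normalize_values(values: np.ndarray, vehicle_mask: np.ndarray) -> np.ndarray:
    """Divide readouts by the mean over vehicle entries (vehicle mean -> 1).

    Generic helper reused for calcium, TMRM and immunoassay relative levels.
    """
    values = np.asarray(values, dtype=float)
    vehicle_mask = np.asarray(vehicle_mask, dtype=bool)
    if not vehicle_mask.any():
        raise ValueError("no vehicle entries to normalize against")
    vmean = values[vehicle_mask].mean()
    if not np.isfinite(vmean) or vmean <= 0:
        raise ValueError(f"vehicle mean must be positive, got {vmean}")
    return values / vmean


def normalize_to_vehicle(
    summaries: Sequence[WellSummary],
    layout: PlateLayout,
    min_responsive_fraction: float = DEFAULT_MIN_RESPONSIVE_FRACTION,
) -> PlateResult:
    """Normalize well readouts to the plate's vehicle wells.

    normalized_value = well mean_peak / mean(valid vehicle wells' mean_peak).
    Wells whose responder fraction falls below ``min_responsive_fraction``
    are flagged invalid (toxicity interference) and excluded from scoring.
    """
    by_address = {s.address: s for s in summaries}
    rows = []
    for w in layout.wells:
        s = by_address.get(w.address)
        if s is None:
            continue
        frac = s.n_responsive / s.n_cells if s.n_cells else 0.0
        valid = s.valid and frac >= min_responsive_fraction
        rows.append(
            {
                "address": w.address,
                "role": w.role.value,
                "compound_id": w.compound_id,
                "replicate_group": w.replicate_group,
                "n_cells": s.n_cells,
                "n_responsive": s.n_responsive,
                "mean_peak": s.mean_peak,
                "valid": valid,
            }
        )
    if not rows:
        raise ValueError("no well summaries match the layout")
    df = pd.DataFrame(rows)

    veh = df[(df["role"] == WellRole.VEHICLE.value) & df["valid"]]
    if veh.empty:
        raise ValueError("no valid vehicle wells on the plate")
    vehicle_mean = float(veh["mean_peak"].mean())
    if vehicle_mean <= 0:
        raise ValueError(f"vehicle mean must be positive, got {vehicle_mean}")
    df["normalized_value"] = df["mean_peak"] / vehicle_mean
    return PlateResult(plate_id=layout.plate_id, wells=df, vehicle_mean=vehicle_mean)


def aggregate_replicates(plate: PlateResult, layout: PlateLayout) -> pd.DataFrame:
    """Per-compound mean +/- sd of the normalized readout over replicate wells.

    Invalid wells are dropped (and counted); compounds with no valid well
    are annotated ``toxicity-interference`` and carry NaN statistics.
    """
    df = plate.wells
    test = df[df["role"] == WellRole.TEST.value]
    rows = []
    for compound_id, grp in test.groupby("compound_id", sort=False):
        ok = grp[grp["valid"]]
        n_valid = len(ok)
        rows.append(
            {
                "compound_id": compound_id,
                "norm_mean": float(ok["normalized_value"].mean()) if n_valid else float("nan"),
                "norm_sd": float(ok["normalized_value"].std(ddof=1)) if n_valid >= 2 else float("nan"),
                "n_wells": n_valid,
                "n_dropped": len(grp) - n_valid,
                "status": "ok" if n_valid else "toxicity-interference",
            }
        )
    return pd.DataFrame(rows)


def call_hits(
    per_compound: pd.DataFrame, threshold: float = DEFAULT_HIT_THRESHOLD
) -> pd.DataFrame:
    """Mark compounds active when their mean normalized readout is strictly
    below the threshold.  Toxicity-interference compounds are not scored."""
    if per_compound.empty:
        raise ValueError("empty per-compound table")
    out = per_compound.copy()
    out["active"] = pd.array(
        (out["norm_mean"] < threshold) & (out["status"] == "ok"), dtype="boolean"
    )
    out.loc[out["status"] != "ok", "active"] = pd.NA
    return out


def qc_plate(
    plate: PlateResult,
    layout: PlateLayout,
    threshold: float = DEFAULT_HIT_THRESHOLD,
) -> QCReport:
    """Each positive control passes iff its normalized readout is below the
    hit threshold; the plate passes iff all controls pass."""
    df = plate.wells
    ctrl = df[(df["role"] == WellRole.POSITIVE_CONTROL.value) & df["valid"]]
    if ctrl.empty:
        return QCReport(
            controls=pd.DataFrame(columns=["compound_id", "normalized_value", "passed"]),
            plate_pass=False,
            reason="no positive-control wells",
        )
    rows = []
    for compound_id, grp in ctrl.groupby("compound_id", sort=False):
        val = float(grp["normalized_value"].mean())
        rows.append(
            {"compound_id": compound_id, "normalized_value": val, "passed": val < threshold}
        )
    table = pd.DataFrame(rows)
    ok = bool(table["passed"].all())
    return QCReport(controls=table, plate_pass=ok, reason="" if ok else "control(s) above threshold")


def _pooled_sd(groups: list[np.ndarray]) -> tuple[float, int]:
    n_total = sum(g.size for g in groups)
    df_ = n_total - len(groups)
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return float(np.sqrt(ss / df_)), df_


def anova_dunnett(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    labels: Sequence[str] | None = None,
    random_state: int | np.random.Generator | None = 0,
) -> list[StatsResult]:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons.

    Raw p-values come from the per-comparison t statistic with the pooled
    variance estimate; adjusted p-values use the equicorrelated
    multivariate-t distribution (via :func:`scipy.stats.dunnett`), which for
    a single comparison reduces exactly to the pooled two-sample t-test.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need a control and at least one treatment group")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    if not 0 <= control_index < len(arrays):
        raise ValueError("control_index out of range")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]

    f_stat, _ = stats.f_oneway(*arrays)
    control = arrays[control_index]
    treatments = [g for i, g in enumerate(arrays) if i != control_index]
    t_labels = [l for i, l in enumerate(labels) if i != control_index]

    sd_pooled, dof = _pooled_sd(arrays)
    t_stats = np.array(
        [
            (g.mean() - control.mean())
            / (sd_pooled * np.sqrt(1.0 / g.size + 1.0 / control.size))
            for g in treatments
        ]
    )
    p_raw = 2.0 * stats.t.sf(np.abs(t_stats), dof)

    if len(treatments) == 1:
        p_adj = p_raw.copy()  # Dunnett with one comparison == pooled t-test
    else:
        res = stats.dunnett(
            *treatments, control=control, random_state=random_state
        )
        p_adj = np.asarray(res.pvalue, dtype=float)
        p_adj = np.minimum(np.maximum(p_adj, p_raw), 1.0)

    return [
        StatsResult(
            comparison=f"{t_labels[i]} vs {labels[control_index]}",
            f_statistic=float(f_stat),
            p_raw=float(p_raw[i]),
            p_adjusted=float(p_adj[i]),
            star=star_annotation(float(p_adj[i])),
        )
        for i in range(len(treatments))
    ]


def star_annotation(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else n.s."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
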
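"""Four-parameter-logistic dose-response and immunoassay calibration
machinery, secretase profiling and mechanism-of-action classification.

Model: response(c) = bottom + (top - bottom) / (1 + (ec50 / c)^hill).
Concentrations are molar; ec50 > 0 and hill != 0.  A negative hill (or
swapped asymptotes) describes a decreasing curve, so IC50s are just the
ec50 of such a fit — no separate functional form.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import CompoundRecord, R1Class, R2Class

__all__ = [
    "FourPLParams",
    "FitResult",
    "ElisaCalibration",
    "SecretaseProfile",
    "Mechanism",
    "MechanismCall",
    "predict_4pl",
    "invert_4pl",
    "fit_4pl",
    "fit_calibration",
    "quantify_samples",
    "build_profile",
    "classify_mechanism",
    "sar_summary",
    "GEA133_TMRM_4PL",
]

ANALYTES = ("abeta38", "abeta40", "abeta42", "sappa", "sappb")

#: electron-withdrawing substituent classes at the first variable position
_EWG_R1 = {R1Class.NITRO, R1Class.HALOGEN, R1Class.TRIFLUOROMETHYL, R1Class.CYANO}
#: aromatic-bearing substituent classes at the second variable position
_AROMATIC_R2 = {R2Class.BENZYLPIPERIDINYL, R2Class.PHENETHYLPIPERIDINYL}


@dataclass(frozen=True)
class FourPLParams:
    bottom: float
    top: float
    ec50: float  # molar
    hill: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill == 0:
            raise ValueError("hill must be nonzero")
        if self.top == self.bottom:
            raise ValueError("top and bottom must differ")


#: TMRM dose-response preset for the demo compound gea_133
#: (half-maximal concentration 4.84 uM; unit-to-doubled response range).
GEA133_TMRM_4PL = FourPLParams(bottom=1.0, top=2.0, ec50=4.84e-6, hill=1.0)


@dataclass
class FitResult:
    params: FourPLParams | None
    converged: bool
    degenerate: bool
    stderr: dict[str, float] | None = None
    residual_sd: float = float("nan")
    message: str = ""


def predict_4pl(params: FourPLParams, c) -> np.ndarray | float:
    """Evaluate the 4PL curve at concentration(s) ``c`` (molar, > 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0")
    out = params.bottom + (params.top - params.bottom) / (
        1.0 + (params.ec50 / c) ** params.hill
    )
    return float(out) if out.ndim == 0 else out


def invert_4pl(params: FourPLParams, signal: float) -> float:
    """Closed-form inverse of the 4PL curve.

    Valid only strictly between the asymptotes; the violated bound is named
    in the error otherwise.
    """
    lo, hi = sorted((params.bottom, params.top))
    if not lo < signal < hi:
        bound = "bottom" if signal <= lo else "top"
        raise ValueError(
            f"signal {signal} outside the open response range "
            f"({lo}, {hi}); violates the {bound} asymptote"
        )
    frac = (params.top - params.bottom) / (signal - params.bottom) - 1.0
    return params.ec50 / frac ** (1.0 / params.hill)


def _4pl_logc(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (log_ec50 - logc)))


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    degenerate_snr: float = 3.0,
) -> FitResult:
    """Unweighted least-squares 4PL fit; concentrations handled on log scale.

    Initialization from the data quartiles: asymptotes from the extreme
    per-concentration means, ec50 from the concentration whose mean response
    is nearest the midpoint, hill sign from the response trend.  Data whose
    response range is below ``degenerate_snr`` times the replicate noise are
    flagged degenerate and not fitted.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses must align")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    uniq = np.unique(conc)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    means = np.array([resp[conc == u].mean() for u in uniq])
    # replicate noise estimate: pooled within-concentration sd
    resid = np.concatenate([resp[conc == u] - resp[conc == u].mean() for u in uniq])
    n_rep_df = resp.size - uniq.size
    noise_sd = float(np.sqrt((resid**2).sum() / n_rep_df)) if n_rep_df > 0 else 0.0
    span = float(means.max() - means.min())
    if span <= 0 or (noise_sd > 0 and span < degenerate_snr * noise_sd):
        return FitResult(
            params=None,
            converged=False,
            degenerate=True,
            message="flat data: response range below the noise floor",
        )

    logc = np.log10(conc)
    increasing = np.corrcoef(np.log10(uniq), means)[0, 1] >= 0
    hill0 = 1.0 if increasing else -1.0
    mid = (means.max() + means.min()) / 2.0
    log_ec50_0 = float(np.log10(uniq[np.argmin(np.abs(means - mid))]))
    p0 = [float(means.min()), float(means.max()), log_ec50_0, hill0]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_4pl_logc, logc, resp, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        return FitResult(
            params=None, converged=False, degenerate=False, message=str(exc)
        )

    bottom, top, log_ec50, hill = popt
    if top == bottom or hill == 0 or not np.isfinite(log_ec50):
        return FitResult(
            params=None, converged=False, degenerate=True, message="collapsed fit"
        )
    params = FourPLParams(float(bottom), float(top), float(10**log_ec50), float(hill))
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    pred = _4pl_logc(logc, *popt)
    dof = max(resp.size - 4, 1)
    return FitResult(
        params=params,
        converged=True,
        degenerate=False,
        stderr={
            "bottom": float(perr[0]),
            "top": float(perr[1]),
            "log10_ec50": float(perr[2]),
            "hill": float(perr[3]),
        },
        residual_sd=float(np.sqrt(((resp - pred) ** 2).sum() / dof)),
    )


@dataclass
class ElisaCalibration:
    """Fitted standard curve for one analyte."""

    analyte: str
    curve: FourPLParams
    valid_range: tuple[float, float]  # [lowest, highest standard], molar
    warning: str = ""


def fit_calibration(
    analyte: str, standard_concs: Sequence[float], signals: Sequence[float]
) -> ElisaCalibration:
    """Fit a 4PL standard curve from calibration standards (>= 6)."""
    conc = np.asarray(standard_concs, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if np.unique(conc).size < 6:
        raise ValueError("calibration needs at least 6 distinct standards")
    if np.allclose(sig, sig[0]):
        raise ValueError("all calibration signals identical; cannot calibrate")
    fit = fit_4pl(conc, sig)
    if not fit.converged or fit.params is None:
        raise ValueError(f"calibration fit failed: {fit.message}")
    span_logs = math.log10(conc.max() / conc.min())
    warning = "" if span_logs >= 3 else (
        f"standards span only {span_logs:.2f} log-units (< 3)"
    )
    return ElisaCalibration(
        analyte=analyte,
        curve=fit.params,
        valid_range=(float(conc.min()), float(conc.max())),
        warning=warning,
    )


def quantify_samples(calib: ElisaCalibration, signals: pd.DataFrame) -> pd.DataFrame:
    """Back-calculate sample concentrations from an immunoassay table.

    ``signals`` needs columns ``sample_id`` and ``signal``; replicate rows
    are averaged before inversion.  Samples outside the standard range are
    flagged, never clipped.
    """
    if not {"sample_id", "signal"} <= set(signals.columns):
        raise ValueError("signals table needs columns sample_id, signal")
    rows = []
    for sid, grp in signals.groupby("sample_id", sort=False):
        mean_sig = float(grp["signal"].mean())
        conc = float("nan")
        flag = "ok"
        try:
            conc = invert_4pl(calib.curve, mean_sig)
        except ValueError as exc:
            flag = "above_range" if "top" in str(exc) else "below_range"
        else:
            lo, hi = calib.valid_range
            if conc < lo:
                flag = "below_range"
            elif conc > hi:
                flag = "above_range"
        rows.append(
            {
                "sample_id": sid,
                "analyte": calib.analyte,
                "mean_signal": mean_sig,
                "concentration": conc,
                "flag": flag,
                "n_replicates": len(grp),
            }
        )
    return pd.DataFrame(rows)


class Mechanism(str, enum.Enum):
    GAMMA_INHIBITOR = "gamma_inhibitor"
    GAMMA_MODULATOR = "gamma_modulator"
    INVERSE_GAMMA_MODULATOR = "inverse_gamma_modulator"
    BETA_CLEAVAGE_REDUCTION = "beta_cleavage_reduction"
    NO_EFFECT = "no_effect"
    UNCLASSIFIED = "unclassified"


@dataclass
class MechanismCall:
    mechanism: Mechanism
    rationale: str


@dataclass
class SecretaseProfile:
    """Vehicle-normalized secretion profile of one compound.

    Levels are relative to the vehicle (vehicle == 1).  ``app_levels`` holds
    abeta38/40/42 from APP-expressing cells; ``c99_levels`` (optional) the
    same analytes from C99-expressing cells, isolating the final cleavage
    step; sappa/sappb (optional) come from wild-type cells.
    """

    compound_id: str
    app_levels: dict[str, float]
    c99_levels: dict[str, float] | None = None
    sappa: float | None = None
    sappb: float | None = None
    stars: dict[str, str] = field(default_factory=dict)
    partial: bool = False

    def __post_init__(self) -> None:
        for d in (self.app_levels, self.c99_levels or {}):
            for k, v in d.items():
                if not v > 0:
                    raise ValueError(f"level {k} must be > 0, got {v}")

    def ratio_42_40(self, context: str = "app") -> float | None:
        levels = self.app_levels if context == "app" else (self.c99_levels or {})
        if "abeta42" in levels and "abeta40" in levels:
            return levels["abeta42"] / levels["abeta40"]
        return None


def build_profile(
    tables: Mapping[str, pd.DataFrame],
    vehicle_id: str,
    compound_id: str,
) -> SecretaseProfile:
    """Assemble a vehicle-normalized profile from quantified assay tables.

    ``tables`` maps context ("app", "c99", "sapp") to a DataFrame with
    columns ``analyte, sample_id, concentration``.  Each analyte's level is
    its mean concentration for the compound divided by the vehicle mean in
    the same context (so absolute calibration scale cancels).
    """
    if "app" not in tables:
        raise ValueError("an 'app' context table is required")

    def normalized_levels(df: pd.DataFrame) -> dict[str, float]:
        out: dict[str, float] = {}
        for analyte, grp in df.groupby("analyte", sort=False):
            veh = grp[grp["sample_id"] == vehicle_id]["concentration"]
            cmp_ = grp[grp["sample_id"] == compound_id]["concentration"]
            if veh.empty:
                raise ValueError(f"vehicle {vehicle_id!r} missing for {analyte}")
            if cmp_.empty:
                continue  # partial profile
            out[str(analyte)] = float(cmp_.mean()) / float(veh.mean())
        return out

    app = normalized_levels(tables["app"])
    c99 = normalized_levels(tables["c99"]) if "c99" in tables else None
    sappa = sappb = None
    if "sapp" in tables:
        sapp = normalized_levels(tables["sapp"])
        sappa = sapp.get("sappa")
        sappb = sapp.get("sappb")
    abeta = {"abeta38", "abeta40", "abeta42"}
    partial = not abeta <= set(app) or (c99 is not None and not abeta <= set(c99))
    return SecretaseProfile(
        compound_id=compound_id,
        app_levels=app,
        c99_levels=c99,
        sappa=sappa,
        sappb=sappb,
        partial=partial,
    )


def classify_mechanism(
    profile: SecretaseProfile,
    down_threshold: float = 0.8,
    up_threshold: float = 1.25,
) -> MechanismCall:
    """Assign exactly one mechanism class to a secretion profile.

    Rules are evaluated in order, first match wins; "down" means a level
    below ``down_threshold``, "up" above ``up_threshold``, "unchanged"
    within the band.
    """
    if not profile.app_levels:
        raise ValueError("profile has no APP-context levels")

    def down(x: float | None) -> bool:
        return x is not None and x < down_threshold

    def up(x: float | None) -> bool:
        return x is not None and x > up_threshold

    def unchanged(x: float | None) -> bool:
        return x is not None and down_threshold <= x <= up_threshold

    app = profile.app_levels
    c99 = profile.c99_levels
    abeta = ("abeta38", "abeta40", "abeta42")
    ratio_app = profile.ratio_42_40("app")
    ratio_c99 = profile.ratio_42_40("c99") if c99 else None
    ratio_main = ratio_c99 if ratio_c99 is not None else ratio_app

    # (1) total-production block at the final cleavage step: everything down
    # in both substrate contexts
    if c99 and all(down(app.get(a)) for a in abeta) and all(
        down(c99.get(a)) for a in abeta
    ):
        return MechanismCall(
            Mechanism.GAMMA_INHIBITOR,
            "all abeta species reduced in both APP and C99 contexts",
        )
    # (2) cleavage-site shift: long species down, short species up, ratio down
    if down(app.get("abeta42")) and up(app.get("abeta38")) and down(ratio_app):
        return MechanismCall(
            Mechanism.GAMMA_MODULATOR,
            "abeta42 down with abeta38 up and 42/40 ratio down",
        )
    # (3) inverse shift: ratio up (C99 context preferred when available)
    if up(ratio_main):
        return MechanismCall(
            Mechanism.INVERSE_GAMMA_MODULATOR, "42/40 ratio increased"
        )
    # (4) upstream cleavage reduction: production down without final-step or
    # ratio changes; direct sAPP evidence required when C99 data are absent
    if all(down(app.get(a)) for a in abeta) and unchanged(ratio_app):
        c99_ok = c99 is None or all(unchanged(c99.get(a)) for a in abeta)
        sapp_seen = profile.sappb is not None
        sapp_ok = down(profile.sappb) and (
            profile.sappa is None or not down(profile.sappa) and not up(profile.sappa)
        )
        if c99_ok and ((c99 is not None and (not sapp_seen or sapp_ok)) or sapp_ok):
            return MechanismCall(
                Mechanism.BETA_CLEAVAGE_REDUCTION,
                "abeta down with final cleavage step and ratio unchanged"
                + ("; sappb down, sappa unchanged" if sapp_seen else ""),
            )
    # (5) nothing moved
    entries: list[float] = list(app.values())
    if c99:
        entries += list(c99.values())
    entries += [x for x in (profile.sappa, profile.sappb, ratio_app, ratio_c99) if x is not None]
    if all(unchanged(x) for x in entries):
        return MechanismCall(Mechanism.NO_EFFECT, "all entries within the band")
    return MechanismCall(Mechanism.UNCLASSIFIED, "no decision rule matched")


def sar_summary(
    compounds: Sequence[CompoundRecord],
    results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group compounds by substituent classes and summarize assay activity.

    ``results`` (optional) needs a ``compound_id`` column; its numeric
    columns are averaged per (r1_class, r2_class) group.  Each group also
    gets a qualitative expectation label: electron-withdrawing R1 combined
    with an aromatic-bearing R2 is expected-active; hydrogen at R1 or a
    merely aliphatic R2 is expected-inactive.
    """
    if not compounds:
        return pd.DataFrame(
            columns=["r1_class", "r2_class", "n_compounds", "expected_label"]
        )
    rows = []
    for rec in compounds:
        rows.append(
            {
                "compound_id": rec.compound_id,
                "r1_class": rec.r1_class.value,
                "r2_class": rec.r2_class.value,
            }
        )
    df = pd.DataFrame(rows)
    if results is not None and not results.empty:
        numeric = results.select_dtypes(include=[np.number]).columns.tolist()
        df = df.merge(
            results[["compound_id", *numeric]], on="compound_id", how="left"
        )

    def label(r1: str, r2: str) -> str:
        r1c, r2c = R1Class(r1), R2Class(r2)
        if r1c is R1Class.HYDROGEN or r2c is R2Class.ALIPHATIC:
            return "expected-inactive"
        if r1c in _EWG_R1 and r2c in _AROMATIC_R2:
            return "expected-active"
        return "indeterminate"

    out_rows = []
    for (r1, r2), grp in df.groupby(["r1_class", "r2_class"], sort=False):
        row = {
            "r1_class": r1,
            "r2_class": r2,
            "n_compounds": len(grp),
            "expected_label": label(r1, r2),
        }
        for col in grp.columns:
            if col in ("compound_id", "r1_class", "r2_class"):
                continue
            row[f"mean_{col}"] = float(grp[col].mean())
        out_rows.append(row)
    return pd.DataFrame(out_rows)
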
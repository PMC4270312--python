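"""End-to-end orchestration: simulate -> segment -> quantify -> screen ->
fit -> classify -> report, driven by a serializable run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AcquisitionSchedule,
    CompoundRecord,
    PlateLayout,
    R1Class,
    R2Class,
    WellRole,
    WellSpec,
    default_schedule,
    write_results,
)
from .kinetics import extract_all_traces, summarize_well
from .pharm import (
    GEA133_TMRM_4PL,
    FourPLParams,
    build_profile,
    classify_mechanism,
    fit_4pl,
    fit_calibration,
    quantify_samples,
    sar_summary,
)
from .screen import (
    DEFAULT_HIT_THRESHOLD,
    aggregate_replicates,
    anova_dunnett,
    call_hits,
    normalize_to_vehicle,
    qc_plate,
)
from .segment import detect_nuclei, exclude_edge_cells, grow_cell_boundaries
from .synth import (
    FieldSpec,
    simulate_dose_table,
    simulate_elisa_plate,
    simulate_screen_plate,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_report", "demo_layout", "demo_compounds"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs besides the seed."""

    seed: int = 0
    n_compounds: int = 24
    n_active: int = 8
    active_scaling: float = 0.7
    n_replicates: int = 4
    responder_threshold: float = 0.1
    hit_threshold: float = DEFAULT_HIT_THRESHOLD
    down_threshold: float = 0.8
    up_threshold: float = 1.25
    genotype_factor: float = 1.5
    trace_noise_cv: float = 0.03
    field: dict[str, Any] = field(default_factory=dict)
    acquisition: dict[str, Any] | None = None
    out_dir: str = "results"

    def schedule(self) -> AcquisitionSchedule:
        if self.acquisition:
            return AcquisitionSchedule.from_dict(self.acquisition)
        return default_schedule()

    def field_spec(self) -> FieldSpec:
        return FieldSpec(**self.field) if self.field else FieldSpec()

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "n_compounds": self.n_compounds,
            "n_active": self.n_active,
            "active_scaling": self.active_scaling,
            "n_replicates": self.n_replicates,
            "responder_threshold": self.responder_threshold,
            "hit_threshold": self.hit_threshold,
            "down_threshold": self.down_threshold,
            "up_threshold": self.up_threshold,
            "genotype_factor": self.genotype_factor,
            "trace_noise_cv": self.trace_noise_cv,
            "field": dict(self.field),
            "acquisition": self.acquisition,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_layout(
    n_compounds: int = 24, n_replicates: int = 4, n_vehicle: int = 8
) -> PlateLayout:
    """A 384-well demo plate: test compounds in replicate columns, vehicle
    wells and the four positive controls."""
    wells: list[WellSpec] = []
    rows = "ABCDEFGHIJKLMNOP"
    idx = 0
    for i in range(n_compounds):
        cid = f"cmpd_{i + 1:03d}"
        for rep in range(n_replicates):
            addr = f"{rows[idx % 16]}{idx // 16 + 1}"
            idx += 1
            wells.append(
                WellSpec(addr, WellRole.TEST, cid, 10e-6, replicate_group=cid)
            )
    for _ in range(n_vehicle):
        addr = f"{rows[idx % 16]}{idx // 16 + 1}"
        idx += 1
        wells.append(WellSpec(addr, WellRole.VEHICLE, replicate_group="vehicle"))
    for ctrl, conc in (("TP", 1e-6), ("CPA", 20e-6), ("TMB-8", 50e-6), ("Bepridil", 20e-6)):
        addr = f"{rows[idx % 16]}{idx // 16 + 1}"
        idx += 1
        wells.append(
            WellSpec(addr, WellRole.POSITIVE_CONTROL, ctrl, conc, replicate_group=ctrl)
        )
    return PlateLayout("demo_plate", 384, tuple(wells))


def demo_compounds(n_compounds: int, n_active: int) -> list[CompoundRecord]:
    """Substituent annotations matching the demo effects: active compounds
    carry electron-withdrawing R1 + aromatic R2, inactives do not."""
    ewg = [R1Class.NITRO, R1Class.HALOGEN, R1Class.TRIFLUOROMETHYL, R1Class.CYANO]
    arom = [R2Class.BENZYLPIPERIDINYL, R2Class.PHENETHYLPIPERIDINYL]
    recs = []
    for i in range(n_compounds):
        cid = f"cmpd_{i + 1:03d}"
        if i < n_active:
            recs.append(CompoundRecord(cid, ewg[i % 4], arom[i % 2], "synthesized"))
        else:
            recs.append(
                CompoundRecord(
                    cid,
                    R1Class.HYDROGEN if i % 2 else R1Class.OTHER,
                    R2Class.ALIPHATIC,
                    "library",
                )
            )
    return recs


def process_plate(
    stacks: dict[str, Any],
    layout: PlateLayout,
    responder_threshold: float = 0.1,
) -> list:
    """Segment every well of a plate and summarize its responder peaks."""
    summaries = []
    for well, stack in stacks.items():
        # segment on the first pre-stimulus frame; labels reused across time
        nuclei = detect_nuclei(stack.nuclear[0])
        if nuclei.n_labels == 0:
            logger.warning("well %s: no nuclei detected", well)
            continue
        cyto = stack.cfp[0] + stack.yfp[0]
        cells, records = grow_cell_boundaries(cyto, nuclei)
        records = exclude_edge_cells(records, cells)
        if not records:
            continue
        traces = extract_all_traces(stack, records, cells.labels)
        if not traces:
            continue
        summaries.append(
            summarize_well(traces, threshold=responder_threshold, address=well)
        )
    return summaries


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full demo pipeline and return the report bundle.

    Identical (config, seed) yields identical tables.
    """
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])

    # --- simulate + screen ------------------------------------------------
    t0 = time.time()
    layout = demo_layout(config.n_compounds, config.n_replicates)
    effects = {
        f"cmpd_{i + 1:03d}": (config.active_scaling if i < config.n_active else 1.0)
        for i in range(config.n_compounds)
    }
    try:
        stacks, truths = simulate_screen_plate(
            layout,
            effects,
            genotype_factor=config.genotype_factor,
            seed=rng,
            field_spec=config.field_spec(),
            schedule=config.schedule(),
            trace_noise_cv=config.trace_noise_cv,
        )
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    tick("simulate", t0)

    t0 = time.time()
    try:
        summaries = process_plate(stacks, layout, config.responder_threshold)
        plate = normalize_to_vehicle(summaries, layout)
        per_compound = aggregate_replicates(plate, layout)
        hits = call_hits(per_compound, config.hit_threshold)
        qc = qc_plate(plate, layout, config.hit_threshold)
    except Exception as exc:
        raise RuntimeError(f"stage 'screen' failed: {exc}") from exc
    tick("screen", t0)

    # --- statistics vs vehicle -------------------------------------------
    t0 = time.time()
    wells = plate.wells
    veh_vals = wells[(wells["role"] == "vehicle") & wells["valid"]][
        "normalized_value"
    ].to_numpy()
    stats_rows = []
    groups = [veh_vals]
    labels = ["vehicle"]
    for cid in layout.compounds():
        vals = wells[(wells["compound_id"] == cid) & wells["valid"]][
            "normalized_value"
        ].to_numpy()
        if vals.size >= 2:
            groups.append(vals)
            labels.append(cid)
    if len(groups) >= 2:
        for res in anova_dunnett(groups, control_index=0, labels=labels, random_state=config.seed):
            stats_rows.append(
                {
                    "comparison": res.comparison,
                    "F": res.f_statistic,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "star": res.star,
                }
            )
    stats_table = pd.DataFrame(stats_rows)
    hits = hits.merge(
        stats_table.assign(
            compound_id=stats_table["comparison"].str.replace(" vs vehicle", "", regex=False)
        )[["compound_id", "p_adjusted", "star"]],
        on="compound_id",
        how="left",
    ) if not stats_table.empty else hits.assign(p_adjusted=np.nan, star="n.s.")
    tick("stats", t0)

    # --- dose-response fit ------------------------------------------------
    t0 = time.time()
    concs = np.logspace(np.log10(0.1e-6), np.log10(30e-6), 6)
    dose = simulate_dose_table(
        GEA133_TMRM_4PL, concs, n_replicates=8, noise_cv=0.05,
        seed=rng, compound_id="gea_133",
    )
    fit = fit_4pl(dose["concentration"], dose["response"])
    dose_fits = pd.DataFrame(
        [
            {
                "compound_id": "gea_133",
                "assay": "tmrm",
                "ec50_uM": fit.params.ec50 * 1e6 if fit.params else np.nan,
                "hill": fit.params.hill if fit.params else np.nan,
                "bottom": fit.params.bottom if fit.params else np.nan,
                "top": fit.params.top if fit.params else np.nan,
                "converged": fit.converged,
            }
        ]
    )
    tick("fit", t0)

    # --- immunoassay + mechanism -----------------------------------------
    t0 = time.time()
    calib_curve = FourPLParams(bottom=50.0, top=20000.0, ec50=200e-12, hill=1.0)
    standards = np.logspace(np.log10(5e-12), np.log10(8e-9), 8)
    # ground-truth secretion profile of a beta-cleavage-reducing compound
    true_levels = {
        "app": {"abeta38": 0.5, "abeta40": 0.5, "abeta42": 0.5},
        "c99": {"abeta38": 1.0, "abeta40": 1.0, "abeta42": 1.0},
        "sapp": {"sappa": 1.0, "sappb": 0.5},
    }
    vehicle_conc = 400e-12
    tables = {}
    for context, levels in true_levels.items():
        frames = []
        for analyte, lvl in levels.items():
            plate_df = simulate_elisa_plate(
                calib_curve,
                standards,
                {"DMSO": vehicle_conc, "gea_133": vehicle_conc * lvl},
                noise_cv=0.02,
                seed=rng,
            )
            stds = plate_df[plate_df["well_type"] == "standard"]
            calib = fit_calibration(analyte, stds["true_concentration"], stds["signal"])
            quant = quantify_samples(calib, plate_df[plate_df["well_type"] == "sample"])
            frames.append(quant.rename(columns={})[["sample_id", "analyte", "concentration"]])
        tables[context] = pd.concat(frames, ignore_index=True)
    profile = build_profile(tables, vehicle_id="DMSO", compound_id="gea_133")
    call = classify_mechanism(profile, config.down_threshold, config.up_threshold)
    mechanisms = pd.DataFrame(
        [
            {
                "compound_id": "gea_133",
                "mechanism": call.mechanism.value,
                "rationale": call.rationale,
            }
        ]
    )
    tick("classify", t0)

    # --- SAR --------------------------------------------------------------
    t0 = time.time()
    compounds = demo_compounds(config.n_compounds, config.n_active)
    sar = sar_summary(
        compounds, hits[["compound_id", "norm_mean"]].astype({"norm_mean": float})
    )
    tick("sar", t0)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "timings_s": timings,
        "total_s": round(time.time() - t_start, 3),
    }
    return {
        "layout": layout,
        "plate": plate,
        "hit_table": hits,
        "qc": qc,
        "stats": stats_table,
        "dose_fits": dose_fits,
        "profile": profile,
        "mechanisms": mechanisms,
        "sar": sar,
        "manifest": manifest,
    }


def write_bundle(bundle: dict[str, Any], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(bundle["hit_table"], out / "hits.csv")
    write_results(bundle["plate"].wells, out / "wells.csv")
    if not bundle["stats"].empty:
        write_results(bundle["stats"], out / "stats.csv")
    write_results(bundle["dose_fits"], out / "dose_fits.csv")
    write_results(bundle["mechanisms"], out / "mechanisms.csv")
    if not bundle["sar"].empty:
        write_results(bundle["sar"], out / "sar.csv")
    write_results(bundle["manifest"], out / "manifest.json")
    (out / "report.md").write_text(render_report(bundle))


def _table(df: pd.DataFrame) -> str:
    if df.empty:
        return "(empty)"
    return "```\n" + df.to_string(index=False) + "\n```"


def render_report(bundle: dict[str, Any]) -> str:
    """Render the bundle as a deterministic markdown summary."""
    hits = bundle["hit_table"]
    qc = bundle["qc"]
    lines = ["# Screening report", ""]
    if not qc.plate_pass:
        lines += ["> **WARNING: plate QC FAILED** — " + (qc.reason or "see controls"), ""]
    n_active = int(hits["active"].fillna(False).sum())
    if n_active == 0:
        lines += ["Zero active compounds at the current threshold.", ""]
    else:
        lines += [f"{n_active} active compound(s).", ""]
    lines += ["## Hit table", "", _table(hits), ""]
    lines += ["## Plate QC", "", _table(qc.controls), ""]
    lines += [f"Plate pass: {qc.plate_pass}", ""]
    if not bundle["stats"].empty:
        lines += [
            "## Statistics (one-way ANOVA + Dunnett vs vehicle)",
            "",
            _table(bundle["stats"]),
            "",
            "n.s., non-significant; *P<0.05, **P<0.01, ***P<0.001.",
            "",
        ]
    lines += ["## Dose-response fits", "", _table(bundle["dose_fits"]), ""]
    lines += ["## Mechanism calls", "", _table(bundle["mechanisms"]), ""]
    if not bundle["sar"].empty:
        lines += ["## SAR summary", "", _table(bundle["sar"]), ""]
    m = bundle["manifest"]
    lines += [
        "## Manifest",
        "",
        f"- package version: {m['package_version']}",
        f"- seed: {m['seed']}",
        f"- config hash: {m['config_hash']}",
        "",
    ]
    return "\n".join(lines)
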
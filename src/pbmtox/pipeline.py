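"""End-to-end orchestration: dose-metric comparison, blood-nadir summary,
regression panels with multiple-testing control, and the NTCP panel.

`run_comparison` consumes per-patient DVHs, weekly bloods and covariates and
emits a result bundle mirroring the standard reporting layout of pelvic
bone-marrow toxicity studies: a group dose-metric comparison (means, SDs,
Mann-Whitney p per structure x level), a baseline/nadir blood summary with
Welch tests, univariate and multivariate regression panels (linear on nadir
counts and ratios, logistic on HT3+) with Holm and Benjamini-Hochberg
decisions per test family, and per-patient Deff/NTCP with CI bounds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .dvh import DVH, STRUCTURES, v_at
from .hematology import ANALYTES, BloodSeries, ht3_flag, ratio_series
from .lkb import LKBParams, PlanPhase, deff_plan, ntcp, ntcp_interval
from .stats import (
    RegressionResult,
    SeparationError,
    CollinearityError,
    family_correction,
    logistic_fit,
    mann_whitney_u,
    ols_fit,
    welch_t,
)

log = logging.getLogger("pbmtox")

GROUPS = ("CRT", "IMRT")
COVARIATE_COLS = ("female", "age", "t34", "node_positive")


@dataclass
class RunConfig:
    """Analysis-side configuration (generator knobs live in GeneratorConfig)."""

    levels: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    lkb: LKBParams = field(
        default_factory=lambda: LKBParams(m_ci=(0.3, 0.4), td50_ci=(28.0, 32.0))
    )
    correction: str = "holm"  # primary method; BH always reported alongside
    alpha: float = 0.05
    crt_phases: tuple = ((30.6, 17), (19.8, 11))
    imrt_fractions: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be ascending")


@dataclass
class ResultBundle:
    dose_metrics: pd.DataFrame
    blood_summary: pd.DataFrame
    weekly_ratios: pd.DataFrame
    regressions: pd.DataFrame
    ntcp_panel: pd.DataFrame
    ntcp_summary: pd.DataFrame
    manifest: dict

    _FRAMES = (
        "dose_metrics", "blood_summary", "weekly_ratios",
        "regressions", "ntcp_panel", "ntcp_summary",
    )

    def to_dict(self) -> dict:
        out = {}
        for name in self._FRAMES:
            df = getattr(self, name)
            data = df.astype(object).where(df.notna(), None)
            out[name] = {"columns": list(df.columns), "data": data.values.tolist()}
        out["manifest"] = self.manifest
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ResultBundle":
        frames = {
            name: pd.DataFrame(d[name]["data"], columns=d[name]["columns"])
            for name in cls._FRAMES
        }
        return cls(manifest=d["manifest"], **frames)


def phases_for(
    group: str, dvhs: Mapping[str, DVH], config: RunConfig
) -> List[PlanPhase]:
    """Reconstruct the fraction-resolved plan from the delivery group:
    two-phase conformal split (proportional dose per phase) or single-phase
    IMRT."""
    if group == "IMRT":
        return [PlanPhase(dict(dvhs), config.imrt_fractions)]
    total = sum(d for d, _ in config.crt_phases)
    return [
        PlanPhase({s: d.scale_doses(dose / total) for s, d in dvhs.items()}, e)
        for dose, e in config.crt_phases
    ]


def _metrics_frame(dvhs, covariates, config) -> pd.DataFrame:
    rows = []
    group_of = dict(zip(covariates["patient_id"], covariates["group"]))
    for pid, per_structure in dvhs.items():
        for s, d in per_structure.items():
            row = {"patient_id": pid, "group": group_of[pid], "structure": s,
                   "volume_ccm": d.total_volume_ccm}
            for lev in config.levels:
                row[f"v{lev:g}"] = v_at(d, lev)
            rows.append(row)
    return pd.DataFrame(rows)


def _nadir_frame(bloods, covariates) -> pd.DataFrame:
    sex = {
        str(r.patient_id): ("female" if r.female else "male")
        for r in covariates.itertuples()
    }
    group_of = dict(zip(covariates["patient_id"], covariates["group"]))
    rows = []
    for pid, s in bloods.items():
        tox = ht3_flag(s, sex=sex[pid])
        row = {"patient_id": pid, "group": group_of[pid], "ht3_observed": int(tox.ht3_plus)}
        for a in ANALYTES:
            row[f"baseline_{a}"] = s.baseline[a]
            row[f"nadir_abs_{a}"] = tox.nadir_absolute[a]
            row[f"nadir_ratio_{a}"] = tox.nadir_ratio[a]
            row[f"nadir_week_{a}"] = tox.nadir_week[a]
        rows.append(row)
    return pd.DataFrame(rows)


def _dose_metric_table(metrics: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rows = []
    for s in STRUCTURES:
        sub = metrics[metrics["structure"] == s]
        if sub.empty:
            continue
        for lev in config.levels:
            col = f"v{lev:g}"
            crt = sub.loc[sub["group"] == "CRT", col].to_numpy()
            imrt = sub.loc[sub["group"] == "IMRT", col].to_numpy()
            test = mann_whitney_u(crt, imrt)
            rows.append(
                {
                    "structure": s, "level_gy": lev,
                    "crt_mean": crt.mean(), "crt_sd": crt.std(ddof=1),
                    "imrt_mean": imrt.mean(), "imrt_sd": imrt.std(ddof=1),
                    "u_statistic": test.statistic, "p": test.p, "method": test.method,
                }
            )
    return pd.DataFrame(rows)


def _blood_summary(nadirs: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for a in ANALYTES:
        row: dict = {"analyte": a}
        for g in GROUPS:
            sub = nadirs[nadirs["group"] == g]
            row[f"{g.lower()}_baseline_mean"] = sub[f"baseline_{a}"].mean()
            for kind in ("abs", "ratio"):
                col = f"nadir_{kind}_{a}"
                row[f"{g.lower()}_nadir_{kind}_mean"] = sub[col].mean()
                row[f"{g.lower()}_nadir_{kind}_min"] = sub[col].min()
                row[f"{g.lower()}_nadir_{kind}_max"] = sub[col].max()
        for kind in ("abs", "ratio"):
            col = f"nadir_{kind}_{a}"
            test = welch_t(
                nadirs.loc[nadirs["group"] == "CRT", col].dropna(),
                nadirs.loc[nadirs["group"] == "IMRT", col].dropna(),
            )
            row[f"p_welch_{kind}"] = test.p
        rows.append(row)
    return pd.DataFrame(rows)


def _weekly_ratio_table(bloods, covariates) -> pd.DataFrame:
    group_of = dict(zip(covariates["patient_id"], covariates["group"]))
    acc: Dict[tuple, list] = {}
    for pid, s in bloods.items():
        for w, vals in ratio_series(s).items():
            for a in ANALYTES:
                if np.isfinite(vals[a]):
                    acc.setdefault((group_of[pid], w, a), []).append(vals[a])
    rows = [
        {"group": g, "week": w, "analyte": a,
         "ratio_mean": float(np.mean(v)), "ratio_sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
         "n": len(v)}
        for (g, w, a), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def _reg_row(r: RegressionResult, **meta) -> dict:
    return {**meta, "beta": r.beta, "se": r.se, "p": r.p, "n_obs": r.n_obs,
            "model": r.model, "note": r.note}


def _nan_row(note: str, n_obs: int, model: str, **meta) -> dict:
    return {**meta, "beta": np.nan, "se": np.nan, "p": np.nan, "n_obs": n_obs,
            "model": model, "note": note}


def _regression_panels(metrics, nadirs, covariates, config) -> pd.DataFrame:
    merged_cov = covariates.set_index("patient_id")
    nad = nadirs.set_index("patient_id")
    rows: List[dict] = []
    for g in GROUPS:
        pids = covariates.loc[covariates["group"] == g, "patient_id"]
        sub_nad = nad.loc[pids]
        cov_g = merged_cov.loc[pids, list(COVARIATE_COLS)].astype(float)
        for s in STRUCTURES:
            msub = (
                metrics[(metrics["group"] == g) & (metrics["structure"] == s)]
                .set_index("patient_id")
                .loc[pids]
            )
            for a in ANALYTES:
                for kind in ("abs", "ratio"):
                    y = sub_nad[f"nadir_{kind}_{a}"].to_numpy(dtype=float)
                    for lev in config.levels:
                        x = msub[f"v{lev:g}"].to_numpy(dtype=float)
                        meta = {"panel": "dose_metric", "group": g, "structure": s,
                                "outcome": a, "outcome_kind": kind, "level_gy": lev,
                                "predictor": f"v{lev:g}"}
                        try:
                            res = ols_fit(y, {f"v{lev:g}": x}, outcome_label=a)[0]
                            rows.append(_reg_row(res, **meta))
                        except (CollinearityError, ValueError) as exc:
                            rows.append(_nan_row(str(exc), len(y), "ols-univariate", **meta))
                        # multivariate: all covariates plus this single metric
                        design = cov_g.copy()
                        design[f"v{lev:g}"] = x
                        meta_mv = dict(meta)
                        try:
                            res_mv = [
                                r for r in ols_fit(y, design, multivariate=True,
                                                   outcome_label=a)
                                if r.predictor == f"v{lev:g}"
                            ][0]
                            rows.append(_reg_row(res_mv, **meta_mv))
                        except (CollinearityError, ValueError) as exc:
                            rows.append(_nan_row(str(exc), len(y), "ols-multivariate", **meta_mv))
                # logistic: observed HT3+ against each metric level
                y_ht3 = sub_nad["ht3_observed"].to_numpy(dtype=float)
                for lev in config.levels:
                    x = msub[f"v{lev:g}"].to_numpy(dtype=float)
                    meta = {"panel": "ht3", "group": g, "structure": s,
                            "outcome": "ht3", "outcome_kind": "binary",
                            "level_gy": lev, "predictor": f"v{lev:g}"}
                    try:
                        res = logistic_fit(y_ht3, {f"v{lev:g}": x}, outcome_label="ht3")[0]
                        rows.append(_reg_row(res, **meta))
                    except (SeparationError, CollinearityError, ValueError) as exc:
                        rows.append(_nan_row(str(exc), len(y_ht3), "logit-univariate", **meta))
    # cohort-wide covariate panel
    cov_all = merged_cov[list(COVARIATE_COLS)].astype(float)
    for a in ANALYTES:
        for kind in ("abs", "ratio"):
            y = nad.loc[cov_all.index, f"nadir_{kind}_{a}"].to_numpy(dtype=float)
            for c in COVARIATE_COLS:
                meta = {"panel": "covariate", "group": "ALL", "structure": "",
                        "outcome": a, "outcome_kind": kind, "level_gy": np.nan,
                        "predictor": c}
                try:
                    res = ols_fit(y, {c: cov_all[c].to_numpy()}, outcome_label=a)[0]
                    rows.append(_reg_row(res, **meta))
                except (CollinearityError, ValueError) as exc:
                    rows.append(_nan_row(str(exc), len(y), "ols-univariate", **meta))
    panel = pd.DataFrame(rows)
    # families: one correction per (model, group, structure, outcome, kind)
    fam_cols = ["model", "panel", "group", "structure", "outcome", "outcome_kind"]
    panel = family_correction(panel, fam_cols, method="holm", alpha=config.alpha)
    panel = family_correction(panel, fam_cols, method="bh", alpha=config.alpha)
    return panel


def _ntcp_panel(dvhs, covariates, config):
    group_of = dict(zip(covariates["patient_id"], covariates["group"]))
    has_ci = config.lkb.m_ci is not None and config.lkb.td50_ci is not None
    rows = []
    for pid, per_structure in dvhs.items():
        phases = phases_for(group_of[pid], per_structure, config)
        d = deff_plan(phases, "whole_pelvis", config.lkb)
        res = ntcp(d, config.lkb)
        lo, hi = ntcp_interval(d, config.lkb) if has_ci else (np.nan, np.nan)
        rows.append(
            {"patient_id": pid, "group": group_of[pid], "structure": "whole_pelvis",
             "deff_gy": d, "ntcp": res.ntcp, "ntcp_low": lo, "ntcp_high": hi}
        )
    panel = pd.DataFrame(rows)
    srows = []
    for g in GROUPS:
        sub = panel[panel["group"] == g]
        srows.append(
            {"group": g, "n": len(sub), "deff_mean": sub["deff_gy"].mean(),
             "ntcp_mean": sub["ntcp"].mean(),
             "ntcp_low_mean": sub["ntcp_low"].mean(),
             "ntcp_high_mean": sub["ntcp_high"].mean()}
        )
    test = welch_t(
        panel.loc[panel["group"] == "CRT", "ntcp"],
        panel.loc[panel["group"] == "IMRT", "ntcp"],
    )
    summary = pd.DataFrame(srows)
    summary["p_welch_ntcp"] = test.p
    return panel, summary


def run_comparison(
    dvhs: Mapping[str, Mapping[str, DVH]],
    bloods: Mapping[str, BloodSeries],
    covariates: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> ResultBundle:
    """Run the full analysis battery on a cohort.

    Parameters
    ----------
    dvhs : {patient_id: {structure: DVH}}
        Total physical-dose DVHs per structure.
    bloods : {patient_id: BloodSeries}
    covariates : DataFrame
        Columns patient_id, group (CRT/IMRT), female, age, t34, node_positive.
    """
    config = config or RunConfig()
    missing = []
    for pid in covariates["patient_id"]:
        if pid not in dvhs:
            missing.append(f"patient {pid}: no DVHs")
        else:
            for s in STRUCTURES:
                if s not in dvhs[pid]:
                    missing.append(f"patient {pid}: missing structure {s}")
        if pid not in bloods:
            missing.append(f"patient {pid}: no blood series")
    if missing:
        raise ValueError(
            "input schema mismatch; run aborted:\n  " + "\n  ".join(missing)
        )
    log.info("analysing cohort of %d patients", len(covariates))
    metrics = _metrics_frame(dvhs, covariates, config)
    nadirs = _nadir_frame(bloods, covariates)
    dose_table = _dose_metric_table(metrics, config)
    blood_table = _blood_summary(nadirs)
    weekly = _weekly_ratio_table(bloods, covariates)
    regressions = _regression_panels(metrics, nadirs, covariates, config)
    ntcp_panel, ntcp_summary = _ntcp_panel(dvhs, covariates, config)
    manifest = {
        "package": "pbmtox",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "n_patients": int(len(covariates)),
        "lib_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ResultBundle(
        dose_metrics=dose_table,
        blood_summary=blood_table,
        weekly_ratios=weekly,
        regressions=regressions,
        ntcp_panel=ntcp_panel,
        ntcp_summary=ntcp_summary,
        manifest=manifest,
    )


#: documented output files of :func:`emit_tables`
OUTPUT_FILES = (
    "dose_metrics.tsv",
    "blood_nadirs.tsv",
    "weekly_ratios.tsv",
    "regressions.tsv",
    "ntcp_panel.tsv",
    "ntcp_summary.tsv",
    "manifest.json",
    "bundle.json",
)

_FLOAT_FORMATS = {
    "dose_metrics.tsv": "%.4g",
    "blood_nadirs.tsv": "%.4g",
    "weekly_ratios.tsv": "%.4g",
    "regressions.tsv": "%.4g",
    "ntcp_panel.tsv": "%.6g",
    "ntcp_summary.tsv": "%.6g",
}


def emit_tables(bundle: ResultBundle, outdir) -> Dict[str, Path]:
    """Write the bundle as TSV tables plus JSON manifest and full bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame_of = {
        "dose_metrics.tsv": bundle.dose_metrics,
        "blood_nadirs.tsv": bundle.blood_summary,
        "weekly_ratios.tsv": bundle.weekly_ratios,
        "regressions.tsv": bundle.regressions,
        "ntcp_panel.tsv": bundle.ntcp_panel,
        "ntcp_summary.tsv": bundle.ntcp_summary,
    }
    paths = {}
    for name, df in frame_of.items():
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMATS[name])
        paths[name] = path
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    paths["manifest.json"] = manifest_path
    bundle_path = outdir / "bundle.json"
    bundle_path.write_text(json.dumps(bundle.to_dict(), sort_keys=True))
    paths["bundle.json"] = bundle_path
    log.info("wrote %d output files to %s", len(paths), outdir)
    return paths
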
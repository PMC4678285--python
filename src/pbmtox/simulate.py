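"""Synthetic CRT/IMRT cohort generator.

Emulates the statistical structure the analysis assumes so every pipeline
stage is testable without clinical data: per-structure pelvic bone-marrow
DVHs whose V5-V25 marginals match the published conformal (CRT) and
intensity-modulated (IMRT) calibration tables; patient covariates (gender,
age, T-stage, nodal status); weekly blood counts with a week-2/3 nadir and
week-4 recovery whose suppression scales with iliac/lumbosacral V10; and
HT3+ outcomes Bernoulli-drawn from the LKB NTCP model so the fitting
machinery can recover its own generating parameters.

Randomness: a single `numpy` Generator consumed in a fixed per-patient
order (covariates -> DVHs by structure -> bloods -> outcome), so a fixed
seed gives bit-identical cohorts and byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .dvh import BIN_WIDTH, DVH, STRUCTURES, dose_metrics, write_dvh_csv
from .hematology import ANALYTES, BloodSeries, write_blood_csv
from .lkb import LKBParams, PlanPhase, deff_plan, ntcp

import pandas as pd

#: V-metric levels used by the calibration tables (Gy)
LEVELS = (5, 10, 15, 20, 25)

# Default calibration: mean/SD of V5..V25 (%) and structure volume (cm^3)
# per delivery group, for whole pelvic bone marrow and its sub-structures.
DOSE_CALIBRATION: Dict[Tuple[str, str], dict] = {
    ("CRT", "whole_pelvis"): {
        "volume": (1399.6, 253.1),
        "v": {5: (60.4, 12.9), 10: (57.3, 12.5), 15: (53.9, 12.0),
              20: (48.7, 11.7), 25: (46.7, 11.7)},
    },
    ("IMRT", "whole_pelvis"): {
        "volume": (1335.6, 245.8),
        "v": {5: (89.8, 4.3), 10: (82.6, 4.7), 15: (78.7, 4.8),
              20: (73.8, 5.2), 25: (64.4, 7.3)},
    },
    ("CRT", "iliac"): {
        "volume": (481.7, 82.2),
        "v": {5: (40.1, 19.5), 10: (35.7, 17.9), 15: (33.2, 16.6),
              20: (30.8, 14.7), 25: (28.4, 14.7)},
    },
    ("IMRT", "iliac"): {
        "volume": (453.3, 73.5),
        "v": {5: (83.0, 7.4), 10: (68.7, 7.4), 15: (61.5, 6.8),
              20: (56.2, 5.6), 25: (47.5, 6.6)},
    },
    ("CRT", "lumbosacral"): {
        "volume": (317.6, 65.1),
        "v": {5: (24.0, 24.0), 10: (19.8, 23.0), 15: (17.6, 22.6),
              20: (16.3, 22.1), 25: (15.1, 21.7)},
    },
    ("IMRT", "lumbosacral"): {
        "volume": (312.7, 62.2),
        "v": {5: (81.1, 9.9), 10: (71.4, 11.5), 15: (67.0, 11.7),
              20: (63.1, 11.9), 25: (59.8, 12.1)},
    },
    ("CRT", "lower_pelvis"): {
        "volume": (599.6, 119.5),
        "v": {5: (95.9, 7.5), 10: (94.4, 9.1), 15: (89.5, 9.4),
              20: (80.0, 8.9), 25: (77.9, 9.0)},
    },
    ("IMRT", "lower_pelvis"): {
        "volume": (569.6, 128.0),
        "v": {5: (100.0, 0.0), 10: (100.0, 0.2), 15: (99.0, 1.6),
              20: (93.9, 6.6), 25: (80.7, 11.2)},
    },
}

# Baseline bloods: mean and observed (min, max); SD back-filled as range/4
# (an assumption: the calibration source prints ranges, not SDs).
BASELINE_BLOODS = {
    "hgb": (12.9, 8.8, 16.0),
    "wcc": (8.0, 3.4, 17.9),
    "anc": (5.1, 1.2, 14.9),
    "plats": (274.5, 144.0, 611.0),
}


def _default_dose_calibration():
    return {k: {"volume": v["volume"], "v": dict(v["v"])} for k, v in DOSE_CALIBRATION.items()}


@dataclass
class GeneratorConfig:
    """All generator knobs with published-calibration defaults.

    Group sizes and dose-metric/baseline-blood distributions default to the
    study conditions (25 CRT / 21 IMRT; the calibration tables above).
    Suppression slopes are per percent V10: WCC 1%/% iliac, ANC 1.5%/% of a
    50:50 iliac/lumbosacral mix, HgB 0.2%/%, platelets 1.1%/% iliac.
    """

    n_crt: int = 25
    n_imrt: int = 21
    level_correlation: float = 0.7  # shared patient effect across V-levels
    dose_calibration: dict = field(default_factory=_default_dose_calibration)
    plan_max_dose: dict = field(
        default_factory=lambda: {"CRT": 50.4, "IMRT": 55.9}  # IMRT: 53.2 x 1.05 hotspot
    )
    crt_phases: tuple = ((30.6, 17), (19.8, 11))  # (phase dose Gy, fractions)
    imrt_fractions: int = 28
    baseline_bloods: dict = field(default_factory=lambda: dict(BASELINE_BLOODS))
    range_sd_divisor: float = 4.0
    female_offset: dict = field(
        default_factory=lambda: {"hgb": 1.0, "wcc": 0.8, "anc": 0.7, "plats": 15.0}
    )
    suppression_slope: dict = field(
        default_factory=lambda: {"wcc": 0.010, "anc": 0.015, "hgb": 0.002, "plats": 0.011}
    )
    anc_lumbosacral_weight: float = 0.5
    weekly_template: tuple = (0.35, 0.7, 1.0, 0.95, 0.6)  # weeks 1..5
    noise_sigma: float = 0.10      # lognormal sigma on the suppression term
    frailty_sigma: float = 0.15    # lognormal sigma of the patient frailty
    biological_cv: float = 0.03    # dose-independent count variability
    ratio_clip: tuple = (0.05, 1.1)
    p_female: float = 27 / 46
    p_t34: float = 23 / 46
    p_node_positive: float = 19 / 46
    age_mean: float = 66.0
    age_sd: float = 10.0
    age_range: tuple = (44.0, 88.0)
    lkb: LKBParams = field(default_factory=LKBParams)

    def __post_init__(self) -> None:
        if self.n_crt < 2 or self.n_imrt < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0 <= self.level_correlation < 1:
            raise ValueError("level_correlation must lie in [0, 1)")


@dataclass
class Covariates:
    female: bool
    age: float
    t34: bool
    node_positive: bool


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # "CRT" or "IMRT"
    covariates: Covariates
    dvhs: Dict[str, DVH]          # total physical-dose DVH per structure
    phases: List[PlanPhase]       # fraction-resolved plan (2 phases CRT, 1 IMRT)
    bloods: BloodSeries
    ht3_true: bool                # simulated ground truth (LKB Bernoulli draw)


@dataclass
class Cohort:
    records: List[PatientRecord]
    config: GeneratorConfig
    seed: int
    truth: dict


# -- truncated-normal helpers -----------------------------------------------


def _tn_ppf(u: float, loc: float, sd: float, lo: float, hi: float) -> float:
    """Inverse CDF of a normal(loc, sd) truncated to [lo, hi]."""
    if sd == 0:
        return loc
    fa = ndtr((lo - loc) / sd)
    fb = ndtr((hi - loc) / sd)
    u = min(max(fa + u * (fb - fa), 1e-15), 1 - 1e-15)
    return loc + sd * ndtri(u)


def _calibrated_loc(mean: float, sd: float, lo: float = 0.0, hi: float = 100.0) -> float:
    """Location of a [lo, hi]-truncated normal whose *mean* equals ``mean``.

    Solving for the location keeps the generated marginals on-calibration
    even where truncation is substantial (e.g. lumbosacral CRT metrics).
    Falls back to ``loc = mean`` where the target sits on a boundary.
    """
    if sd == 0 or not (lo < mean < hi):
        return mean

    def f(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        za, zb = ndtr(a), ndtr(b)
        phi_a = np.exp(-0.5 * a * a) / np.sqrt(2 * np.pi)
        phi_b = np.exp(-0.5 * b * b) / np.sqrt(2 * np.pi)
        return loc + sd * (phi_a - phi_b) / (zb - za) - mean

    try:
        return brentq(f, mean - 8 * sd, mean + 8 * sd, xtol=1e-10)
    except ValueError:
        return mean


def _pav_decreasing(values: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences (L2,
    equal weights); preserves the vector sum."""
    vals = list(values.astype(float))
    blocks = [[v, 1] for v in vals]  # (sum, count)
    out: list = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] / out[-2][1] < out[-1][0] / out[-1][1]:
            s, c = out.pop()
            out[-1][0] += s
            out[-1][1] += c
    res = []
    for s, c in out:
        res.extend([s / c] * c)
    return np.asarray(res)


class CohortGenerator:
    """Deterministic synthetic-cohort factory for a :class:`GeneratorConfig`."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or GeneratorConfig()
        self._loc_cache: Dict[Tuple[float, float], float] = {}

    # -- pieces ------------------------------------------------------------

    def _loc(self, mean: float, sd: float) -> float:
        key = (mean, sd)
        if key not in self._loc_cache:
            self._loc_cache[key] = _calibrated_loc(mean, sd)
        return self._loc_cache[key]

    def generate_dvh(self, group: str, structure: str, rng: np.random.Generator) -> DVH:
        """Draw one structure DVH whose V5..V25 follow the calibrated,
        cross-level-correlated truncated normals (monotone by isotonic
        projection), with a linear cumulative decay above 25 Gy to the plan
        maximum dose."""
        cfg = self.config
        cal = cfg.dose_calibration[(group, structure)]
        rho = cfg.level_correlation
        for _ in range(100):
            z0 = rng.standard_normal()
            vals = np.empty(len(LEVELS))
            for j, lev in enumerate(LEVELS):
                mu, sd = cal["v"][lev]
                z = np.sqrt(rho) * z0 + np.sqrt(1 - rho) * rng.standard_normal()
                loc = self._loc(mu, sd)
                vals[j] = _tn_ppf(ndtr(z), loc, sd, 0.0, 100.0)
            vals = np.clip(_pav_decreasing(vals), 0.0, 100.0)
            if np.all(np.diff(vals) <= 1e-9):
                break
        vmu, vsd = cal["volume"]
        volume = _tn_ppf(rng.random(), vmu, vsd, 1e-6, np.inf)
        dmax = cfg.plan_max_dose[group]
        knot_d = np.concatenate([[0.0], np.asarray(LEVELS, dtype=float), [dmax]])
        knot_c = np.concatenate([[1.0], vals / 100.0, [0.0]])
        grid = np.round(np.arange(0, int(round(dmax / BIN_WIDTH)) + 1) * BIN_WIDTH, 10)
        c = np.interp(grid, knot_d, knot_c)
        frac = c - np.append(c[1:], 0.0)
        return DVH(grid, frac, total_volume_ccm=volume, structure=structure)

    def generate_covariates(self, rng: np.random.Generator) -> Covariates:
        cfg = self.config
        female = bool(rng.random() < cfg.p_female)
        age = _tn_ppf(rng.random(), cfg.age_mean, cfg.age_sd, *cfg.age_range)
        t34 = bool(rng.random() < cfg.p_t34)
        node = bool(rng.random() < cfg.p_node_positive)
        return Covariates(female=female, age=age, t34=t34, node_positive=node)

    def _phases(self, group: str, dvhs: Mapping[str, DVH]) -> List[PlanPhase]:
        cfg = self.config
        if group == "IMRT":
            return [PlanPhase(dict(dvhs), cfg.imrt_fractions)]
        total = sum(d for d, _ in cfg.crt_phases)
        return [
            PlanPhase({s: d.scale_doses(phase_dose / total) for s, d in dvhs.items()}, e)
            for phase_dose, e in cfg.crt_phases
        ]

    def simulate_bloods(
        self,
        dvhs: Mapping[str, DVH],
        cov: Covariates,
        rng: np.random.Generator,
    ) -> BloodSeries:
        """Weekly counts: baseline draw, then ratio r_w = clip(1 - S_a g_w eps)
        times a small dose-independent biological noise.  Susceptibility S_a
        scales with iliac (and for ANC lumbosacral) V10 and a patient frailty."""
        cfg = self.config
        iliac_v10 = dose_metrics(dvhs["iliac"]).v10
        ls_v10 = dose_metrics(dvhs["lumbosacral"]).v10
        w = cfg.anc_lumbosacral_weight
        driver = {
            "wcc": iliac_v10,
            "anc": (1 - w) * iliac_v10 + w * ls_v10,
            "hgb": iliac_v10,
            "plats": iliac_v10,
        }
        baseline = {}
        for a in ANALYTES:
            mu, lo, hi = cfg.baseline_bloods[a]
            sd = (hi - lo) / cfg.range_sd_divisor
            if cov.female:
                mu = mu - cfg.female_offset[a]
            baseline[a] = _tn_ppf(rng.random(), mu, sd, lo, hi)
        frailty = float(np.exp(rng.normal(0.0, cfg.frailty_sigma)))
        weekly = {}
        for wk, g in enumerate(cfg.weekly_template, start=1):
            row = {}
            for a in ANALYTES:
                s_a = cfg.suppression_slope[a] * driver[a] * frailty  # per % V10
                eps = float(np.exp(rng.normal(0.0, cfg.noise_sigma)))
                r = float(np.clip(1.0 - s_a * g * eps, *cfg.ratio_clip))
                bio = float(np.exp(rng.normal(0.0, cfg.biological_cv)))
                row[a] = baseline[a] * r * bio
            weekly[wk] = row
        return BloodSeries(baseline=baseline, weekly=weekly)

    def simulate_ht3_outcome(
        self, phases: Sequence[PlanPhase], rng: np.random.Generator
    ) -> bool:
        """Bernoulli draw with probability NTCP(plan Deff of whole-pelvis BM)."""
        p = ntcp(deff_plan(phases, "whole_pelvis", self.config.lkb), self.config.lkb).ntcp
        return bool(rng.random() < p)

    # -- whole cohorts -----------------------------------------------------

    def generate_cohort(self, seed: int) -> Cohort:
        cfg = self.config
        rng = np.random.default_rng(seed)
        records: List[PatientRecord] = []
        specs = [("CRT", i) for i in range(cfg.n_crt)] + [
            ("IMRT", i) for i in range(cfg.n_imrt)
        ]
        for group, i in specs:
            pid = f"{group}{i + 1:03d}"
            cov = self.generate_covariates(rng)
            dvhs = {s: self.generate_dvh(group, s, rng) for s in STRUCTURES}
            bloods = self.simulate_bloods(dvhs, cov, rng)
            phases = self._phases(group, dvhs)
            ht3 = self.simulate_ht3_outcome(phases, rng)
            records.append(
                PatientRecord(pid, group, cov, dvhs, phases, bloods, ht3)
            )
        truth = {
            "lkb": {"n": cfg.lkb.n, "m": cfg.lkb.m, "td50": cfg.lkb.td50,
                    "alpha_beta": cfg.lkb.alpha_beta},
            "suppression_slope": dict(cfg.suppression_slope),
            "weekly_template": list(cfg.weekly_template),
            "ht3_true": {r.patient_id: r.ht3_true for r in records},
        }
        return Cohort(records=records, config=cfg, seed=seed, truth=truth)


def covariates_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "group": r.group,
            "female": int(r.covariates.female),
            "age": r.covariates.age,
            "t34": int(r.covariates.t34),
            "node_positive": int(r.covariates.node_positive),
        }
        for r in cohort.records
    ]
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, outdir) -> Dict[str, Path]:
    """Write dvh.csv, bloods.csv, covariates.csv and truth.json.

    The DVH file holds total physical-dose DVHs; phase structure is implied
    by the group (two-phase conformal split, single-phase IMRT) and recorded
    in truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dvh": outdir / "dvh.csv",
        "bloods": outdir / "bloods.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.json",
    }
    write_dvh_csv(paths["dvh"], {r.patient_id: r.dvhs for r in cohort.records})
    write_blood_csv(paths["bloods"], {r.patient_id: r.bloods for r in cohort.records})
    covariates_frame(cohort).to_csv(paths["covariates"], index=False)
    truth = dict(cohort.truth)
    truth["seed"] = cohort.seed
    truth["crt_phases"] = [list(p) for p in cohort.config.crt_phases]
    truth["imrt_fractions"] = cohort.config.imrt_fractions
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> Cohort:
    """Convenience wrapper: build a generator and draw one cohort."""
    return CohortGenerator(config).generate_cohort(seed)
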
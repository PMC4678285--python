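"""Weekly blood-count processing: ratios, nadirs, CTCAE v4.0 grading, HT3+.

Counts are haemoglobin (HgB, g/dL) and white cells / neutrophils / platelets
(WCC / ANC / plats, x10^9/L), collected at baseline (week 0) and weekly
during radiotherapy.  Ratios divide each week's count by baseline; the nadir
is the minimum observed on-treatment value.  Cytopenias are graded with the
CTCAE v4.0 thresholds; HT3+ means any lineage reaching grade 3 or higher at
any observed week.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import math

import numpy as np
import pandas as pd

ANALYTES = ("hgb", "wcc", "anc", "plats")

#: analyte -> toxicity lineage name
LINEAGES = {
    "hgb": "anemia",
    "wcc": "leukopenia",
    "anc": "neutropenia",
    "plats": "thrombocytopenia",
}

# CTCAE v4.0 cytopenia thresholds, strict "<" at every boundary: a value
# below the first threshold it undercuts takes that grade.  HgB grade 4
# requires clinical criteria absent from count data, so the maximum
# assignable anemia grade here is 3 (documented limitation).
_GRADE_TABLE = {
    "wcc": ((1.0, 4), (2.0, 3), (3.0, 2)),
    "anc": ((0.5, 4), (1.0, 3), (1.5, 2)),
    "plats": ((25.0, 4), (50.0, 3), (75.0, 2)),
    "hgb": ((8.0, 3), (10.0, 2)),
}

#: default lower limits of normal (grade-1 boundary); HgB is sex-specific
DEFAULT_LLN = {"wcc": 4.0, "anc": 1.5, "plats": 150.0, "hgb_female": 12.0, "hgb_male": 13.5}


def ctcae_grade(
    analyte: str,
    value: float,
    lln: Optional[float] = None,
    sex: str = "female",
) -> int:
    """CTCAE v4.0 cytopenia grade (0-4) for one count.

    ``lln`` overrides the default lower limit of normal (the grade-1
    boundary); for HgB the default is sex-specific (12.0 female / 13.5 male).
    Boundaries are strict: a count exactly at a threshold takes the milder
    grade (ANC exactly 1.0 is grade 2, not 3).
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}")
    if not np.isfinite(value) or value < 0:
        raise ValueError("value must be a non-negative number")
    for threshold, grade in _GRADE_TABLE[analyte]:
        if value < threshold:
            return grade
    if lln is None:
        lln = DEFAULT_LLN["hgb_female" if sex == "female" else "hgb_male"] \
            if analyte == "hgb" else DEFAULT_LLN[analyte]
    return 1 if value < lln else 0


def _clean_week(values: Mapping[str, float]) -> Dict[str, float]:
    out = {}
    for a in ANALYTES:
        v = values.get(a)
        out[a] = float(v) if v is not None and not (isinstance(v, float) and math.isnan(v)) \
            else float("nan")
    return out


@dataclass(frozen=True)
class BloodSeries:
    """Baseline plus weekly blood counts for one patient.

    ``baseline`` maps analyte -> count (all present and positive); ``weekly``
    maps week index (1..6) -> analyte -> count, with NaN for missing values
    and whole weeks allowed to be absent.
    """

    baseline: Mapping[str, float]
    weekly: Mapping[int, Mapping[str, float]]

    def __post_init__(self) -> None:
        base = {a: float(self.baseline[a]) for a in ANALYTES}
        if any(not v > 0 for v in base.values()):
            raise ValueError("all baseline counts must be present and positive")
        weekly = {}
        for w, vals in self.weekly.items():
            w = int(w)
            if w < 1:
                raise ValueError("weekly indices start at 1 (week 0 is baseline)")
            if w in weekly:
                raise ValueError(f"duplicate week {w}")
            row = _clean_week(vals)
            if any(v < 0 for v in row.values() if not math.isnan(v)):
                raise ValueError("weekly counts must be non-negative")
            weekly[w] = row
        if not weekly:
            raise ValueError("at least one on-treatment week is required")
        object.__setattr__(self, "baseline", base)
        object.__setattr__(self, "weekly", dict(sorted(weekly.items())))


@dataclass(frozen=True)
class ToxicityAssessment:
    """Per-lineage maximum grades, HT3+ flag and per-analyte nadir summary."""

    max_grade: Dict[str, int]
    ht3_plus: bool
    nadir_absolute: Dict[str, float]
    nadir_ratio: Dict[str, float]
    nadir_week: Dict[str, int]

    def __post_init__(self) -> None:
        if self.ht3_plus != any(g >= 3 for g in self.max_grade.values()):
            raise ValueError("ht3_plus must equal 'any lineage grade >= 3'")


def ratio_series(s: BloodSeries) -> Dict[int, Dict[str, float]]:
    """Week-indexed count ratios: each week's count divided by baseline."""
    return {
        w: {a: vals[a] / s.baseline[a] for a in ANALYTES}
        for w, vals in s.weekly.items()
    }


def nadir(s: BloodSeries):
    """Per-analyte (absolute nadir, ratio nadir, earliest nadir week).

    Missing weeks/values are skipped; an analyte with no observed value at
    all yields NaN nadirs and week 0.
    """
    absolute: Dict[str, float] = {}
    ratio: Dict[str, float] = {}
    week: Dict[str, int] = {}
    for a in ANALYTES:
        best_w, best_v = 0, float("nan")
        for w, vals in s.weekly.items():
            v = vals[a]
            if math.isnan(v):
                continue
            if math.isnan(best_v) or v < best_v - 1e-12:
                best_w, best_v = w, v
        absolute[a] = best_v
        ratio[a] = best_v / s.baseline[a]
        week[a] = best_w
    return absolute, ratio, week


def ht3_flag(
    s: BloodSeries,
    lln: Optional[Mapping[str, float]] = None,
    sex: str = "female",
) -> ToxicityAssessment:
    """Grade every observed on-treatment count and flag acute HT3+.

    Baseline is not graded.  HT3+ is true iff any lineage reaches grade >= 3
    at any observed week; co-occurring lineages are reported separately.
    """
    lln = dict(lln or {})
    max_grade = {lineage: 0 for lineage in LINEAGES.values()}
    for _, vals in s.weekly.items():
        for a in ANALYTES:
            v = vals[a]
            if math.isnan(v):
                continue
            g = ctcae_grade(a, v, lln=lln.get(a), sex=sex)
            lineage = LINEAGES[a]
            max_grade[lineage] = max(max_grade[lineage], g)
    absolute, ratio, week = nadir(s)
    return ToxicityAssessment(
        max_grade=max_grade,
        ht3_plus=any(g >= 3 for g in max_grade.values()),
        nadir_absolute=absolute,
        nadir_ratio=ratio,
        nadir_week=week,
    )


# ---------------------------------------------------------------------------
# CSV I/O: patient_id, week (0 = baseline), hgb, wcc, anc, plats
# ---------------------------------------------------------------------------


def read_blood_csv(path) -> Dict[str, BloodSeries]:
    """Read weekly bloods; empty cells are missing values."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "week", *ANALYTES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out: Dict[str, BloodSeries] = {}
    for pid, sub in df.groupby("patient_id", sort=False):
        rows = {int(r.week): {a: getattr(r, a) for a in ANALYTES} for r in sub.itertuples()}
        if 0 not in rows:
            raise ValueError(f"{path}: patient {pid} has no baseline (week 0) row")
        baseline = rows.pop(0)
        out[str(pid)] = BloodSeries(baseline=baseline, weekly=rows)
    return out


def write_blood_csv(path, series: Mapping[str, BloodSeries]) -> None:
    rows = []
    for pid, s in series.items():
        rows.append({"patient_id": pid, "week": 0, **s.baseline})
        for w, vals in s.weekly.items():
            rows.append({"patient_id": pid, "week": w, **vals})
    pd.DataFrame(rows).to_csv(path, index=False)


def nadir_table(series: Mapping[str, BloodSeries], sex: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Long-format per-patient nadir/grade summary (one row per analyte)."""
    sex = sex or {}
    rows = []
    for pid, s in series.items():
        tox = ht3_flag(s, sex=sex.get(pid, "female"))
        for a in ANALYTES:
            rows.append(
                {
                    "patient_id": pid,
                    "analyte": a,
                    "baseline": s.baseline[a],
                    "nadir_absolute": tox.nadir_absolute[a],
                    "nadir_ratio": tox.nadir_ratio[a],
                    "nadir_week": tox.nadir_week[a],
                    "max_grade": tox.max_grade[LINEAGES[a]],
                    "ht3_plus": tox.ht3_plus,
                }
            )
    return pd.DataFrame(rows)
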
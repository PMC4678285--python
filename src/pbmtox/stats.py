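"""Group comparisons, regression models and multiple-testing control.

All p-values are two-sided.  The Mann-Whitney U test compares dose-metric
distributions between delivery groups (exact when both groups are small and
tie-free, normal approximation with tie and continuity corrections
otherwise); Welch's unequal-variance t-test compares blood-count nadirs.
Linear and logistic regressions relate dose metrics and covariates to nadir
counts and HT3+.  Corrections are applied within families of related tests:
step-down Holm (family-wise error, the default) or Benjamini-Hochberg
(false-discovery rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

#: smallest reported p-value; exact fits report this floor instead of 0
P_FLOOR = 1e-12

_EXACT_MAX_N = 8


class SeparationError(RuntimeError):
    """Complete separation in logistic regression: coefficients diverge."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix; message names the offending predictors."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    n_x: int
    n_y: int
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    outcome: str
    beta: float
    se: float
    p: float
    n_obs: int
    model: str = "ols"
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.se) and self.se < 0:
            raise ValueError("se must be non-negative")
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of rank arrangements when min(n_x, n_y) <= 8 and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and min(x.size, y.size) <= _EXACT_MAX_N
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        method="mann-whitney-exact" if exact else "mann-whitney-normal",
        n_x=int(x.size),
        n_y=int(y.size),
    )


def welch_t(x, y) -> TestResult:
    """Two-sided unpaired t-test assuming unequal variances
    (Welch-Satterthwaite degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate: no within-group variance
        if np.isclose(x.mean(), y.mean()):
            return TestResult(0.0, 1.0, "welch-t", x.size, y.size, note="degenerate: zero variance")
        return TestResult(
            float("inf"), P_FLOOR, "welch-t", x.size, y.size,
            note="degenerate: zero variance, unequal means",
        )
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), "welch-t", int(x.size), int(y.size))


def _check_design(X: pd.DataFrame) -> None:
    const = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0]
    if const:
        raise CollinearityError(f"constant predictor(s): {const}")
    mat = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        corr = X.corr().abs()
        pairs = [
            (a, b)
            for i, a in enumerate(X.columns)
            for b in X.columns[i + 1 :]
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise CollinearityError(f"rank-deficient design; collinear predictors: {pairs}")


def _as_frame(predictors) -> pd.DataFrame:
    if isinstance(predictors, pd.DataFrame):
        return predictors.astype(float)
    if isinstance(predictors, Mapping):
        return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in predictors.items()})
    arr = np.asarray(predictors, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def ols_fit(
    outcome,
    predictors,
    multivariate: bool = False,
    outcome_label: str = "y",
) -> list[RegressionResult]:
    """Ordinary least squares with intercept; one result per predictor.

    With ``multivariate=False`` each predictor is fitted in its own simple
    regression; with ``multivariate=True`` a single joint model is fitted.
    P-values come from the t distribution with the residual degrees of
    freedom and are floored at 1e-12 (exact fits report the floor, never 0).
    """
    y = np.asarray(outcome, dtype=float)
    X = _as_frame(predictors)
    if len(X) != len(y):
        raise ValueError("outcome and predictors must have equal length")
    groups = [list(X.columns)] if multivariate else [[c] for c in X.columns]
    out: list[RegressionResult] = []
    for cols in groups:
        sub = X[cols]
        if len(y) <= len(cols) + 1:
            raise ValueError("need n_obs > n_predictors + 1")
        _check_design(sub)
        res = sm.OLS(y, sm.add_constant(sub)).fit()
        for c in cols:
            se = float(res.bse[c])
            p = P_FLOOR if se == 0 or not np.isfinite(res.pvalues[c]) \
                else max(float(res.pvalues[c]), P_FLOOR)
            out.append(
                RegressionResult(
                    predictor=c, outcome=outcome_label,
                    beta=float(res.params[c]), se=se, p=p,
                    n_obs=int(res.nobs),
                    model="ols-multivariate" if multivariate else "ols-univariate",
                )
            )
    return out


def logistic_fit(
    outcome,
    predictors,
    multivariate: bool = False,
    outcome_label: str = "y",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> list[RegressionResult]:
    """Maximum-likelihood logistic regression (Newton/IRLS) with Wald tests.

    Raises :class:`SeparationError` on complete separation (diverging
    coefficients or non-convergence) rather than emitting silent output.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = _as_frame(predictors)
    if len(X) != len(y):
        raise ValueError("outcome and predictors must have equal length")
    groups = [list(X.columns)] if multivariate else [[c] for c in X.columns]
    out: list[RegressionResult] = []
    for cols in groups:
        sub = X[cols]
        _check_design(sub)
        try:
            with warnings.catch_warnings():
                # separation is detected and raised explicitly below
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(sub)).fit(
                    disp=0, method="newton", maxiter=max_iter, tol=tol,
                    warn_convergence=False,
                )
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"separation fitting {cols}: {exc}") from exc
        if (not res.mle_retvals.get("converged", False)) or np.any(
            np.abs(res.params.to_numpy()) > 50
        ):
            raise SeparationError(
                f"logistic fit for {cols} did not converge (likely separation)"
            )
        for c in cols:
            out.append(
                RegressionResult(
                    predictor=c, outcome=outcome_label,
                    beta=float(res.params[c]), se=float(res.bse[c]),
                    p=max(float(res.pvalues[c]), P_FLOOR), n_obs=int(res.nobs),
                    model="logit-multivariate" if multivariate else "logit-univariate",
                )
            )
    return out


def holm_bonferroni(p_values: Mapping[str, float], alpha: float = 0.05) -> Dict[str, bool]:
    """Step-down Holm decisions mapped back to labels.

    Sorted ascending, p_(i) is compared against alpha/(k-i+1); rejection
    stops at the first failure.
    """
    labels = list(p_values)
    p = np.asarray([p_values[k] for k in labels], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return dict(zip(labels, (bool(r) for r in reject)))


def benjamini_hochberg(p_values: Mapping[str, float], alpha: float = 0.05) -> Dict[str, bool]:
    """Step-up Benjamini-Hochberg (FDR) decisions mapped back to labels."""
    labels = list(p_values)
    p = np.asarray([p_values[k] for k in labels], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return dict(zip(labels, (bool(r) for r in reject)))


def family_correction(
    results: pd.DataFrame,
    family_cols: Sequence[str],
    p_col: str = "p",
    method: str = "holm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply Holm (default) or BH within each family of tests independently.

    ``family_cols`` typically form the key (group, structure, analyte); tests
    in different families never share a correction.  Returns a copy with a
    boolean ``reject_<method>`` column.
    """
    if method not in ("holm", "bh"):
        raise ValueError("method must be 'holm' or 'bh'")
    correct = holm_bonferroni if method == "holm" else benjamini_hochberg
    out = results.copy()
    col = f"reject_{method}"
    out[col] = False
    for _, idx in out.groupby(list(family_cols), dropna=False).groups.items():
        sub = out.loc[idx, p_col]
        valid = sub[np.isfinite(sub)]
        if len(valid) == 0:
            continue
        decisions = correct({str(i): float(v) for i, v in valid.items()}, alpha=alpha)
        for i in valid.index:
            out.loc[i, col] = decisions[str(i)]
    return out
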
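"""Lyman-Kutcher-Burman (LKB) NTCP engine for pelvic bone marrow.

The model collapses a structure's dose distribution to a generalized
equivalent uniform dose

    Deff = (sum_i v_i * d_i**(1/n)) ** n

over 0.1 Gy DVH bins, after correcting each bin dose to its 2 Gy/fraction
equivalent with the linear-quadratic model,

    LQED2_i = D_i * (1 + (D_i/e) / (a/b)) / (1 + 2 / (a/b)),

where ``e`` is the number of fractions and a/b the tissue's alpha/beta ratio
(10 Gy for pelvic bone marrow).  The complication probability is a probit in
the effective dose:

    NTCP = Phi(x),   x = (Deff - TD50) / (m * TD50).

With the volume-effect exponent constrained to n = 1 (fully parallel organ)
the adopted haematologic-toxicity parameters are m = 0.09 and TD50 = 30 Gy.
For two-phase conformal plans Deff is the sum of the per-phase Deff values.

The maximum-likelihood fit of (m, TD50) from binary toxicity outcomes is
exposed as the sklearn-style estimator :class:`LKBProbitModel`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.special import ndtr
from sklearn.base import BaseEstimator

from .dvh import DVH

#: adopted pelvic-bone-marrow alpha/beta ratio in Gy
PBM_ALPHA_BETA = 10.0

_PROB_CLIP = 1e-12
_CHI2_1DF_95_HALF = 1.92  # profile-likelihood drop for a 95% CI


def _sorted_ci(ci, point, name):
    if ci is None:
        return None
    lo, hi = sorted(float(v) for v in ci)
    if not (lo <= point <= hi):
        warnings.warn(
            f"{name} point estimate {point} lies outside its CI ({lo}, {hi}); "
            "bounds kept as supplied",
            UserWarning,
            stacklevel=3,
        )
    return (lo, hi)


@dataclass(frozen=True)
class LKBParams:
    """LKB parameter set: n (volume effect), m (slope), TD50 (Gy), alpha/beta (Gy).

    Optional 95% CI bounds for m and TD50 are sorted on construction; a point
    estimate outside its CI triggers a warning but is kept as supplied.
    """

    n: float = 1.0
    m: float = 0.09
    td50: float = 30.0
    alpha_beta: float = PBM_ALPHA_BETA
    m_ci: Optional[Tuple[float, float]] = None
    td50_ci: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name in ("n", "m", "td50", "alpha_beta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "m_ci", _sorted_ci(self.m_ci, self.m, "m"))
        object.__setattr__(self, "td50_ci", _sorted_ci(self.td50_ci, self.td50, "TD50"))


@dataclass(frozen=True)
class PlanPhase:
    """One treatment phase: per-structure DVHs plus its fraction count ``e``.

    Delivered plans carry integer fraction counts; fractional values are
    accepted so that exact 2 Gy/fraction constructions (``e = D/2``) can be
    expressed in identity checks.
    """

    dvhs: Mapping[str, DVH]
    n_fractions: float

    def __post_init__(self) -> None:
        if not self.n_fractions >= 1:
            raise ValueError("n_fractions must be >= 1")
        for s, d in self.dvhs.items():
            if not isinstance(d, DVH):
                raise TypeError(f"structure {s!r} does not hold a DVH")


@dataclass(frozen=True)
class NTCPResult:
    deff: float
    x: float
    ntcp: float
    ci: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ntcp <= 1.0):
            raise ValueError("ntcp must lie in [0, 1]")
        if self.ci is not None and not (self.ci[0] - 1e-12 <= self.ntcp <= self.ci[1] + 1e-12):
            raise ValueError("CI must contain the point NTCP")


def lqed2(dose, n_fractions, alpha_beta: float = PBM_ALPHA_BETA):
    """Linear-quadratic 2 Gy/fraction equivalent of a total bin dose.

    ``dose`` may be a scalar or array of total doses accumulated over
    ``n_fractions`` fractions.  Exactly the identity when dose/n_fractions
    equals 2 Gy.  ``n_fractions`` may be fractional (used by identity checks);
    plan phases carry integer counts.
    """
    if not n_fractions >= 1:
        raise ValueError("n_fractions must be >= 1")
    if not alpha_beta > 0:
        raise ValueError("alpha_beta must be positive")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = d * (1.0 + (d / n_fractions) / alpha_beta) / (1.0 + 2.0 / alpha_beta)
    return float(out) if np.isscalar(dose) else out


def geud(doses, volume_fractions, n: float) -> float:
    """Generalized EUD ``(sum v_i d_i**(1/n))**n`` over DVH bins."""
    if not n > 0:
        raise ValueError("n must be positive")
    d = np.asarray(doses, dtype=float)
    v = np.asarray(volume_fractions, dtype=float)
    return float(np.dot(v, d ** (1.0 / n)) ** n)


def deff(phase: PlanPhase, structure: str, params: LKBParams) -> float:
    """Effective (generalized equivalent uniform) dose for one phase, in Gy.

    Bin doses are LQED2-corrected with the phase's fraction count before the
    power-mean reduction; with n = 1 this is the volume-weighted mean LQED2.
    """
    if structure not in phase.dvhs:
        raise ValueError(f"structure {structure!r} missing from phase")
    d = phase.dvhs[structure]
    lq = lqed2(d.bin_doses, phase.n_fractions, params.alpha_beta)
    return geud(lq, d.volume_fraction, params.n)


def deff_plan(phases: Sequence[PlanPhase], structure: str, params: LKBParams) -> float:
    """Plan-level Deff: the sum of per-phase Deff values (two-phase conformal
    plans are combined by summation; a single phase reduces to :func:`deff`)."""
    if len(phases) == 0:
        raise ValueError("at least one phase is required")
    return float(sum(deff(p, structure, params) for p in phases))


def ntcp(deff_gy: float, params: LKBParams) -> NTCPResult:
    """Probit NTCP at an effective dose (closed-form normal CDF, erf-based)."""
    x = (deff_gy - params.td50) / (params.m * params.td50)
    return NTCPResult(deff=float(deff_gy), x=float(x), ntcp=float(ndtr(x)))


def ntcp_interval(deff_gy: float, params: LKBParams) -> Tuple[float, float]:
    """NTCP range over the four (m, TD50) CI-endpoint combinations.

    Both CIs must be present.  The returned interval always contains the
    point NTCP.
    """
    if params.m_ci is None or params.td50_ci is None:
        raise ValueError("both m_ci and td50_ci are required")
    vals = [ntcp(deff_gy, LKBParams(params.n, m, t, params.alpha_beta)).ntcp
            for m in params.m_ci for t in params.td50_ci]
    vals.append(ntcp(deff_gy, params).ntcp)
    return (min(vals), max(vals))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


class NonIdentifiableError(ValueError):
    """All outcomes identical: (m, TD50) cannot be estimated."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged within the iteration cap."""


def _neg_loglik(m: float, td50: float, d: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(ndtr((d - td50) / (m * td50)), _PROB_CLIP, 1.0 - _PROB_CLIP)
    return -float(np.dot(y, np.log(p)) + np.dot(1.0 - y, np.log1p(-p)))


class LKBProbitModel(BaseEstimator):
    """Sklearn-style maximum-likelihood LKB probit dose-response model.

    ``fit`` takes per-patient effective doses (Gy) and binary toxicity
    outcomes and estimates the slope ``m`` and position ``TD50`` by
    maximizing the Bernoulli log-likelihood with the volume-effect exponent
    ``n`` held fixed.  Derivative-free simplex searches from nine grid-spread
    starts inside the box m in [0.01, 1], TD50 in [5, 100] Gy; the best
    converged start wins, ties broken by smallest m.

    Parameters
    ----------
    n : float
        Fixed volume-effect exponent (kept for provenance; the fit acts on
        already-reduced effective doses).
    m_bounds, td50_bounds : tuple of float
        Search box for the two free parameters.
    tol : float
        Convergence tolerance on the log-likelihood.
    max_iter : int
        Iteration cap per simplex start.
    compute_ci : bool
        If True, profile-likelihood 95% CIs (log-likelihood drop 1.92) are
        computed after the fit.

    Attributes
    ----------
    m_, td50_ : float
        Maximum-likelihood estimates.
    loglik_ : float
        Log-likelihood at the optimum.
    m_ci_, td50_ci_ : tuple of float
        Profile-likelihood 95% CIs (only when ``compute_ci``).
    """

    def __init__(
        self,
        n: float = 1.0,
        m_bounds: Tuple[float, float] = (0.01, 1.0),
        td50_bounds: Tuple[float, float] = (5.0, 100.0),
        tol: float = 1e-8,
        max_iter: int = 2000,
        compute_ci: bool = True,
    ):
        self.n = n
        self.m_bounds = m_bounds
        self.td50_bounds = td50_bounds
        self.tol = tol
        self.max_iter = max_iter
        self.compute_ci = compute_ci

    # -- internal ----------------------------------------------------------

    def _objective(self, theta, d, y):
        m, td50 = theta
        mb, tb = self.m_bounds, self.td50_bounds
        if not (mb[0] <= m <= mb[1] and tb[0] <= td50 <= tb[1]):
            # distance penalty keeps the simplex inside the box
            pen = (
                max(0.0, mb[0] - m, m - mb[1]) + max(0.0, tb[0] - td50, td50 - tb[1])
            )
            m = min(max(m, mb[0]), mb[1])
            td50 = min(max(td50, tb[0]), tb[1])
            return _neg_loglik(m, td50, d, y) + 1e3 * pen
        return _neg_loglik(m, td50, d, y)

    def _profile_nll(self, fixed: str, value: float, d, y) -> float:
        if fixed == "m":
            res = minimize_scalar(
                lambda t: _neg_loglik(value, t, d, y),
                bounds=self.td50_bounds, method="bounded",
                options={"xatol": 1e-6},
            )
        else:
            res = minimize_scalar(
                lambda m: _neg_loglik(m, value, d, y),
                bounds=self.m_bounds, method="bounded",
                options={"xatol": 1e-8},
            )
        return float(res.fun)

    def _profile_ci(self, fixed: str, hat: float, bounds, d, y):
        target = -self.loglik_ + _CHI2_1DF_95_HALF

        def f(v):
            return self._profile_nll(fixed, v, d, y) - target

        out = []
        for edge in bounds:
            lo, hi = sorted((hat, edge))
            if f(edge) <= 0:
                out.append(edge)  # CI truncated at the search box
            else:
                out.append(brentq(f, lo, hi, xtol=1e-5))
        return (min(out), max(out))

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        d = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if np.any(d <= 0):
            raise ValueError("effective doses must be positive")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("outcomes must be binary (0/1)")
        if len(np.unique(y)) < 2:
            raise NonIdentifiableError(
                "all outcomes identical; (m, TD50) is not identifiable"
            )

        m_starts = np.geomspace(self.m_bounds[0] * 2, self.m_bounds[1] / 2, 3)
        t_starts = np.linspace(*self.td50_bounds, 5)[1:-1]
        candidates = []
        for m0 in m_starts:
            for t0 in t_starts:
                res = minimize(
                    self._objective, x0=[m0, t0], args=(d, y), method="Nelder-Mead",
                    options={
                        "xatol": 1e-7, "fatol": self.tol,
                        "maxiter": self.max_iter, "maxfev": self.max_iter,
                    },
                )
                if res.success:
                    candidates.append(res)
        if not candidates:
            raise ConvergenceError("no optimizer start converged")
        best_fun = min(res.fun for res in candidates)
        # ties on the log-likelihood broken by smallest m
        best = min(
            (res for res in candidates if res.fun <= best_fun + self.tol),
            key=lambda r: r.x[0],
        )
        self.m_, self.td50_ = (float(best.x[0]), float(best.x[1]))
        self.loglik_ = -float(best.fun)
        self.n_starts_converged_ = len(candidates)
        if self.compute_ci:
            self.m_ci_ = self._profile_ci("m", self.m_, self.m_bounds, d, y)
            self.td50_ci_ = self._profile_ci("td50", self.td50_, self.td50_bounds, d, y)
        return self

    def predict_proba(self, X):
        d = np.asarray(X, dtype=float).reshape(-1)
        p = ndtr((d - self.td50_) / (self.m_ * self.td50_))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean per-observation Bernoulli log-likelihood."""
        d = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        return -_neg_loglik(self.m_, self.td50_, d, y) / len(y)

    def to_params(self, alpha_beta: float = PBM_ALPHA_BETA) -> LKBParams:
        return LKBParams(
            n=self.n, m=self.m_, td50=self.td50_, alpha_beta=alpha_beta,
            m_ci=getattr(self, "m_ci_", None), td50_ci=getattr(self, "td50_ci_", None),
        )


def fit_lkb_ml(
    deffs: Sequence[float],
    outcomes: Sequence[int],
    n_fixed: float = 1.0,
    compute_ci: bool = True,
) -> LKBParams:
    """Functional wrapper around :class:`LKBProbitModel`; returns LKBParams
    with profile-likelihood CIs."""
    model = LKBProbitModel(n=n_fixed, compute_ci=compute_ci).fit(deffs, outcomes)
    return model.to_params()
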
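import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.base import clone

from oracles import geud_direct
from pbmtox.dvh import DVH
from pbmtox.lkb import (
    LKBParams,
    LKBProbitModel,
    NonIdentifiableError,
    PlanPhase,
    deff,
    deff_plan,
    fit_lkb_ml,
    geud,
    lqed2,
    ntcp,
    ntcp_interval,
)


def uniform_phase(dose, n_fractions, structure="whole_pelvis"):
    return PlanPhase({structure: DVH.from_points({dose: 1.0})}, n_fractions)


class TestLqed2:
    @pytest.mark.parametrize(
        "di,e,ab,expected",
        [
            (56.0, 28, 10.0, 56.0),                 # 2 Gy/fraction identity
            (28.0, 28, 10.0, 28.0 * 1.1 / 1.2),     # 1 Gy/fraction
            (0.0, 28, 10.0, 0.0),
        ],
    )
    def test_examples(self, di, e, ab, expected):
        assert lqed2(di, e, ab) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_two_gray_per_fraction_identity(self, di):
        if di < 2.0:
            return
        assert lqed2(di, di / 2.0, 10.0) == pytest.approx(di, rel=1e-14)

    def test_zero_fractions_rejected(self):
        with pytest.raises(ValueError):
            lqed2(30.0, 0, 10.0)


class TestDeff:
    def test_uniform_dose_2gy_per_fraction(self):
        phase = uniform_phase(50.0, 25)
        assert deff(phase, "whole_pelvis", LKBParams(n=1.0)) == pytest.approx(50.0)

    def test_weighted_mean_example(self):
        # bins already on the LQED2 scale, n = 1 -> volume-weighted mean
        assert geud([20.0, 40.0], [0.5, 0.5], 1.0) == pytest.approx(30.0)

    def test_volume_effect_example(self):
        assert geud([20.0, 40.0], [0.5, 0.5], 0.5) == pytest.approx(np.sqrt(1000.0))

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 60.0), st.floats(0.01, 1.0)),
            min_size=1,
            max_size=10,
        )
    )
    def test_geud_matches_direct_oracle(self, bins):
        doses = [d for d, _ in bins]
        weights = np.asarray([w for _, w in bins])
        fracs = weights / weights.sum()
        for n in (1.0, 0.5, 0.25, 2.0):
            assert geud(doses, fracs, n) == pytest.approx(
                geud_direct(doses, fracs, n), rel=1e-12
            )

    def test_n1_equals_mean_lqed2(self):
        rng = np.random.default_rng(0)
        fracs = rng.dirichlet(np.ones(40))
        doses = np.round(np.arange(40) * 0.1 + 20.0, 10)
        phase = PlanPhase({"s": DVH(doses, fracs)}, 20)
        params = LKBParams(n=1.0)
        expected = float(np.dot(fracs, lqed2(doses, 20, params.alpha_beta)))
        assert deff(phase, "s", params) == pytest.approx(expected, rel=1e-12)

    def test_bin_split_invariance(self):
        params = LKBParams(n=0.7)
        whole = geud([20.0, 40.0], [0.5, 0.5], params.n)
        split = geud([20.0, 20.0, 40.0], [0.2, 0.3, 0.5], params.n)
        assert split == pytest.approx(whole, rel=1e-12)

    def test_missing_structure(self):
        with pytest.raises(ValueError, match="missing"):
            deff(uniform_phase(30.0, 15), "iliac", LKBParams())


class TestDeffPlan:
    def test_single_phase_reduces_to_deff(self):
        phase = uniform_phase(56.0, 28)
        params = LKBParams()
        assert deff_plan([phase], "whole_pelvis", params) == deff(
            phase, "whole_pelvis", params
        )

    def test_two_phase_additivity(self):
        # each phase uniform 15 Gy at 2 Gy/fraction -> summed Deff of 30 Gy
        phases = [uniform_phase(15.0, 7.5), uniform_phase(15.0, 7.5)]
        assert deff_plan(phases, "whole_pelvis", LKBParams(n=1.0)) == pytest.approx(30.0)

    def test_phase_order_irrelevant(self):
        phases = [uniform_phase(30.6, 17), uniform_phase(19.8, 11)]
        params = LKBParams()
        assert deff_plan(phases, "whole_pelvis", params) == pytest.approx(
            deff_plan(phases[::-1], "whole_pelvis", params), rel=1e-14
        )

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            deff_plan([], "whole_pelvis", LKBParams())


class TestNtcp:
    @pytest.mark.parametrize(
        "deff_gy,expected_x",
        [(30.0, 0.0), (32.7, 1.0), (27.3, -1.0)],
    )
    def test_probit_examples(self, deff_gy, expected_x):
        res = ntcp(deff_gy, LKBParams(m=0.09, td50=30.0))
        assert res.x == pytest.approx(expected_x, abs=1e-12)
        assert res.ntcp == pytest.approx(norm.cdf(expected_x), abs=1e-12)

    @given(st.floats(0.02, 0.5))
    def test_half_probability_at_td50_for_any_slope(self, m):
        assert ntcp(30.0, LKBParams(m=m, td50=30.0)).ntcp == pytest.approx(0.5, abs=1e-14)

    def test_strictly_increasing_in_deff(self):
        params = LKBParams()
        # away from floating-point saturation of the normal CDF tails
        doses = np.linspace(24, 36, 200)
        vals = [ntcp(d, params).ntcp for d in doses]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestNtcpInterval:
    def test_degenerate_cis_collapse_to_point(self):
        p = LKBParams(m_ci=(0.09, 0.09), td50_ci=(30.0, 30.0))
        lo, hi = ntcp_interval(30.0, p)
        assert lo == hi == pytest.approx(0.5)

    def test_td50_ci_straddles_half(self):
        p = LKBParams(m_ci=(0.09, 0.09), td50_ci=(28.0, 32.0))
        lo, hi = ntcp_interval(30.0, p)
        assert lo < 0.5 < hi

    def test_wider_m_ci_never_narrows(self):
        narrow = LKBParams(m_ci=(0.08, 0.10), td50_ci=(28.0, 32.0))
        wide = LKBParams(m_ci=(0.05, 0.20), td50_ci=(28.0, 32.0))
        for d in (22.0, 30.0, 38.0):
            lo_n, hi_n = ntcp_interval(d, narrow)
            lo_w, hi_w = ntcp_interval(d, wide)
            assert lo_w <= lo_n + 1e-12 and hi_w >= hi_n - 1e-12

    def test_missing_ci_rejected(self):
        with pytest.raises(ValueError):
            ntcp_interval(30.0, LKBParams(td50_ci=(28.0, 32.0)))


class TestParams:
    def test_ci_sorted(self):
        p = LKBParams(td50_ci=(32.0, 28.0))
        assert p.td50_ci == (28.0, 32.0)

    def test_point_outside_ci_warns_but_keeps_bounds(self):
        with pytest.warns(UserWarning, match="outside"):
            p = LKBParams(m=0.09, m_ci=(0.4, 0.3))
        assert p.m_ci == (0.3, 0.4)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            LKBParams(m=0.0)


def simulate_outcomes(seed, n=2000, m=0.09, td50=30.0):
    rng = np.random.default_rng(seed)
    d = rng.uniform(20.0, 40.0, n)
    p = norm.cdf((d - td50) / (m * td50))
    return d, (rng.random(n) < p).astype(int)


class TestMaximumLikelihoodFit:
    def test_recovers_generating_parameters(self):
        d, y = simulate_outcomes(seed=11)
        params = fit_lkb_ml(d, y, compute_ci=False)
        assert params.m == pytest.approx(0.09, abs=0.02)
        assert params.td50 == pytest.approx(30.0, abs=1.0)

    def test_recovers_alternate_truth(self):
        d, y = simulate_outcomes(seed=12, td50=35.0)
        params = fit_lkb_ml(d, y, compute_ci=False)
        assert params.td50 == pytest.approx(35.0, abs=1.0)
        assert params.td50 > 32.5  # clearly away from the standard 30 Gy

    def test_loglik_beats_grid_oracle(self):
        d, y = simulate_outcomes(seed=13, n=300)
        model = LKBProbitModel(compute_ci=False).fit(d, y)
        ms = np.linspace(0.01, 1.0, 50)
        ts = np.linspace(5.0, 100.0, 50)
        p = norm.cdf(
            (d[None, None, :] - ts[None, :, None]) / (ms[:, None, None] * ts[None, :, None])
        )
        p = np.clip(p, 1e-12, 1 - 1e-12)
        grid_ll = (y * np.log(p) + (1 - y) * np.log1p(-p)).sum(axis=-1)
        assert model.loglik_ >= grid_ll.max() - 1e-6

    def test_profile_cis_cover_truth_here(self):
        d, y = simulate_outcomes(seed=14)
        model = LKBProbitModel().fit(d, y)
        assert model.m_ci_[0] < model.m_ < model.m_ci_[1]
        assert model.td50_ci_[0] < model.td50_ < model.td50_ci_[1]
        assert model.td50_ci_[0] < 30.0 < model.td50_ci_[1]

    def test_all_identical_outcomes_flagged(self):
        with pytest.raises(NonIdentifiableError):
            fit_lkb_ml([25.0, 30.0, 35.0], [0, 0, 0])

    def test_nonpositive_deff_rejected(self):
        with pytest.raises(ValueError):
            fit_lkb_ml([0.0, 30.0], [0, 1])

    def test_sklearn_protocol(self):
        model = LKBProbitModel(compute_ci=False)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        d, y = simulate_outcomes(seed=15, n=500)
        cloned.fit(d, y)
        proba = cloned.predict_proba([25.0, 30.0, 35.0])
        assert proba.shape == (3, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert set(cloned.predict([20.0, 40.0])) <= {0, 1}
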
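import json

import numpy as np
import pytest

from pbmtox.dvh import STRUCTURES, DVH, dose_metrics, read_dvh_csv
from pbmtox.hematology import read_blood_csv
from pbmtox.lkb import LKBParams
from pbmtox.simulate import (
    CohortGenerator,
    GeneratorConfig,
    covariates_frame,
    write_cohort,
)
from pbmtox.stats import ols_fit


@pytest.fixture(scope="module")
def generator():
    return CohortGenerator()


class TestCohortShape:
    def test_default_group_sizes(self, default_cohort):
        groups = [r.group for r in default_cohort.records]
        assert len(groups) == 46
        assert groups.count("CRT") == 25
        assert groups.count("IMRT") == 21

    def test_phase_structure_by_group(self, default_cohort):
        for r in default_cohort.records:
            expected = 2 if r.group == "CRT" else 1
            assert len(r.phases) == expected
            if r.group == "CRT":
                assert [p.n_fractions for p in r.phases] == [17, 11]

    def test_determinism_bit_identical(self, generator, default_cohort):
        again = generator.generate_cohort(7)
        for a, b in zip(default_cohort.records, again.records):
            assert a.patient_id == b.patient_id
            assert a.ht3_true == b.ht3_true
            assert a.covariates == b.covariates
            for s in STRUCTURES:
                assert np.array_equal(
                    a.dvhs[s].volume_fraction, b.dvhs[s].volume_fraction
                )
            assert a.bloods.baseline == b.bloods.baseline

    def test_all_dvhs_valid_and_monotone(self, default_cohort):
        for r in default_cohort.records:
            for s, d in r.dvhs.items():
                assert d.volume_fraction.sum() == pytest.approx(1.0, abs=1e-6)
                m = dose_metrics(d)
                assert m.v5 >= m.v10 >= m.v15 >= m.v20 >= m.v25


class TestCovariates:
    def test_female_fraction_calibrated(self, generator):
        rng = np.random.default_rng(100)
        draws = [generator.generate_covariates(rng) for _ in range(10_000)]
        assert np.mean([c.female for c in draws]) == pytest.approx(27 / 46, abs=0.02)
        assert np.mean([c.t34 for c in draws]) == pytest.approx(23 / 46, abs=0.02)
        assert np.mean([c.node_positive for c in draws]) == pytest.approx(19 / 46, abs=0.02)

    def test_ages_within_printed_range(self, generator):
        rng = np.random.default_rng(101)
        ages = [generator.generate_covariates(rng).age for _ in range(2000)]
        assert min(ages) >= 44.0 and max(ages) <= 88.0
        assert np.mean(ages) == pytest.approx(66.0, abs=1.0)


class TestDvhCalibration:
    N = 600

    @pytest.mark.parametrize("group,target", [("IMRT", 82.6), ("CRT", 57.3)])
    def test_whole_pelvis_v10_anchor(self, generator, group, target):
        rng = np.random.default_rng(200)
        v10 = [
            dose_metrics(generator.generate_dvh(group, "whole_pelvis", rng)).v10
            for _ in range(self.N)
        ]
        assert np.mean(v10) == pytest.approx(target, abs=1.5)

    @pytest.mark.parametrize("group", ["CRT", "IMRT"])
    @pytest.mark.parametrize("structure", STRUCTURES)
    def test_all_levels_near_calibration(self, generator, group, structure):
        # The monotone (isotonic) projection trades a small per-level bias for
        # valid V5 >= ... >= V25 orderings; the bias is largest at the outer
        # levels of structures whose adjacent level means overlap within
        # their SDs, so the tolerance here is absolute, not 1 SE.
        rng = np.random.default_rng(201)
        cal = generator.config.dose_calibration[(group, structure)]
        draws = [generator.generate_dvh(group, structure, rng) for _ in range(self.N)]
        for lev in (5, 10, 15, 20, 25):
            observed = np.mean([getattr(dose_metrics(d), f"v{lev}") for d in draws])
            assert observed == pytest.approx(cal["v"][lev][0], abs=4.0)

    def test_volume_calibrated(self, generator):
        rng = np.random.default_rng(202)
        vols = [
            generator.generate_dvh("CRT", "whole_pelvis", rng).total_volume_ccm
            for _ in range(self.N)
        ]
        assert np.mean(vols) == pytest.approx(1399.6, rel=0.02)


class TestBloods:
    def test_nadir_week_two_to_three(self):
        cfg = GeneratorConfig(n_crt=100, n_imrt=100)
        cohort = CohortGenerator(cfg).generate_cohort(30)
        weeks = []
        for r in cohort.records:
            wcc = {w: v["wcc"] for w, v in r.bloods.weekly.items()}
            weeks.append(min(wcc, key=wcc.get))
        assert int(np.median(weeks)) in (2, 3)
        # week 4 recovers relative to the week-3 nadir on average
        ratios = np.array([
            [r.bloods.weekly[w]["wcc"] / r.bloods.baseline["wcc"] for w in (3, 4)]
            for r in cohort.records
        ])
        assert ratios[:, 1].mean() > ratios[:, 0].mean()

    def test_zero_dose_patient_unsuppressed(self, generator):
        rng = np.random.default_rng(40)
        flat = {s: DVH.from_points({0.0: 1.0}, 500.0, s) for s in STRUCTURES}
        cov = generator.generate_covariates(rng)
        bloods = generator.simulate_bloods(flat, cov, rng)
        for w, vals in bloods.weekly.items():
            for a, v in vals.items():
                assert v / bloods.baseline[a] == pytest.approx(1.0, abs=0.15)

    def test_wcc_suppression_slope_recovered(self):
        cfg = GeneratorConfig(n_crt=200, n_imrt=2)
        cohort = CohortGenerator(cfg).generate_cohort(41)
        crt = [r for r in cohort.records if r.group == "CRT"]
        x = np.array([dose_metrics(r.dvhs["iliac"]).v10 for r in crt])
        y = np.array([
            min(v["wcc"] for v in r.bloods.weekly.values()) / r.bloods.baseline["wcc"]
            for r in crt
        ])
        res = ols_fit(y, {"iliac_v10": x})[0]
        assert abs(res.beta - (-0.01)) < 3 * res.se

    def test_female_baseline_offset(self):
        cfg = GeneratorConfig(n_crt=300, n_imrt=2)
        cohort = CohortGenerator(cfg).generate_cohort(42)
        females = [r.bloods.baseline["hgb"] for r in cohort.records if r.covariates.female]
        males = [r.bloods.baseline["hgb"] for r in cohort.records if not r.covariates.female]
        assert np.mean(females) < np.mean(males)


class TestOutcomes:
    def test_bernoulli_half_at_td50(self, generator):
        rng = np.random.default_rng(50)
        # uniform 30 Gy at 2 Gy/fraction: Deff = TD50 = 30 -> NTCP 0.5
        from pbmtox.lkb import PlanPhase

        phase = PlanPhase({"whole_pelvis": DVH.from_points({30.0: 1.0})}, 15)
        draws = [generator.simulate_ht3_outcome([phase], rng) for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.03)

    def test_huge_td50_never_toxic(self):
        cfg = GeneratorConfig(lkb=LKBParams(td50=1e6))
        cohort = CohortGenerator(cfg).generate_cohort(51)
        assert not any(r.ht3_true for r in cohort.records)

    def test_lkb_recovery_end_to_end(self):
        # outcomes drawn from the generator's own LKB truth are recovered by
        # the maximum-likelihood fit
        from pbmtox.lkb import deff_plan, fit_lkb_ml

        cfg = GeneratorConfig(n_crt=700, n_imrt=700)
        cohort = CohortGenerator(cfg).generate_cohort(52)
        deffs = np.array([
            deff_plan(r.phases, "whole_pelvis", cfg.lkb) for r in cohort.records
        ])
        y = np.array([int(r.ht3_true) for r in cohort.records])
        params = fit_lkb_ml(deffs, y, compute_ci=False)
        assert params.td50 == pytest.approx(30.0, abs=2.0)
        assert params.m == pytest.approx(0.09, abs=0.04)


class TestFilesRoundTrip:
    def test_written_files_reload_cleanly(self, default_cohort, tmp_path):
        paths = write_cohort(default_cohort, tmp_path)
        dvhs = read_dvh_csv(paths["dvh"])
        bloods = read_blood_csv(paths["bloods"])
        truth = json.loads(paths["truth"].read_text())
        cov = covariates_frame(default_cohort)
        assert set(dvhs) == set(cov["patient_id"])
        assert set(bloods) == set(cov["patient_id"])
        assert truth["lkb"]["td50"] == 30.0
        r0 = default_cohort.records[0]
        assert dvhs[r0.patient_id]["iliac"].allclose(r0.dvhs["iliac"], atol=1e-9)
        for a, v in r0.bloods.baseline.items():
            assert bloods[r0.patient_id].baseline[a] == pytest.approx(v, rel=1e-9)

    def test_same_seed_byte_identical_files(self, generator, tmp_path):
        a = write_cohort(generator.generate_cohort(9), tmp_path / "a")
        b = write_cohort(generator.generate_cohort(9), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()
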
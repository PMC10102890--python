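"""Prognosis-parameter curves: point estimates, closed-form variance
agreement, recovery of analytic truths, and logical bounds."""
import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from survode import (
    Cohort,
    cause_specific_curves,
    conditional_survival,
    crmtl,
    nelson_aalen,
    read_curve,
    rmrl,
    solve,
    write_curve,
)
from survode.params import PrognosisCurve, cif_system, rmrl_system, survival_system
from survode.simulate import ScenarioSpec, generate_cohort, truth
from survode.cohort import augment_time_component


class TestSystems:
    def test_survival_solution_hand_example(self, toy4):
        hz = nelson_aalen(toy4, "all")
        path = solve(survival_system().system, hz)
        assert path.state_at(3.0)[0] == pytest.approx(0.375)

    def test_cif_hand_example(self, toy4):
        hz = nelson_aalen(toy4, (1, 2))
        path = solve(cif_system().system, hz)
        s, cc, co = path.x[-1]
        assert cc == pytest.approx(0.625)  # 1*(1/4) + 0.375*1
        assert co == pytest.approx(0.375)  # 0.75*(1/2)

    @pytest.mark.parametrize("seed", range(5))
    def test_cif_conservation(self, random_cohorts, seed):
        """S + C^c + C^o = 1 at every grid time on any cohort."""
        hz = nelson_aalen(random_cohorts(seed), (1, 2))
        path = solve(cif_system().system, hz)
        np.testing.assert_allclose(path.x.sum(axis=1), 1.0, atol=1e-12)

    def test_rmrl_integral_hand_example(self, toy4):
        hz = augment_time_component(nelson_aalen(toy4, "all"), 0.25, horizon=4.0)
        path = solve(rmrl_system().system, hz)
        # R(4) = 1*1 + 0.75*2 + 0.375*1
        assert path.x[-1, 1] == pytest.approx(2.875, abs=1e-10)

    def test_zero_hazard_r_equals_t(self):
        coh = Cohort(time=[5.0, 5.0], event=[0, 0])
        hz = nelson_aalen(coh, "all")
        aug = augment_time_component(hz, 0.5, horizon=5.0)
        path = solve(rmrl_system().system, aug)
        assert path.x[-1, 0] == 1.0
        assert path.x[-1, 1] == pytest.approx(5.0, abs=1e-12)


class TestConditionalSurvival:
    def test_hand_ratio(self, toy4):
        curve = conditional_survival(toy4, delta=2.0, horizon=4.0)
        assert curve.at(1.0) == pytest.approx(0.5)

    def test_delta_zero_is_one_with_zero_variance(self, random_cohorts):
        curve = conditional_survival(random_cohorts(2), delta=0.0)
        ok = curve.defined
        np.testing.assert_allclose(curve.estimate[ok], 1.0, atol=1e-12)
        np.testing.assert_allclose(curve.variance[ok], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_km_ratio_from_oracle(self, random_cohorts, seed):
        """The point estimate is the classical conditional-survival
        estimator: a ratio of Kaplan-Meier values."""
        coh = random_cohorts(seed, n=150)
        delta = 1.5
        curve = conditional_survival(coh, delta=delta)
        kmf = KaplanMeierFitter().fit(coh.time, coh.event > 0)
        for i, t in enumerate(curve.t_grid):
            if curve.undefined_mask[i]:
                continue
            s_t = float(kmf.survival_function_at_times(t).iloc[0])
            s_td = float(kmf.survival_function_at_times(t + delta).iloc[0])
            assert curve.estimate[i] == pytest.approx(s_td / s_t, abs=1e-12)

    def test_exponential_memorylessness(self):
        """Under a constant hazard the conditional survival curve is flat
        in t at e^{-lambda*delta}."""
        spec = ScenarioSpec(
            n=2000, lambda_cancer=0.3, lambda_other=0.2,
            censoring_rate=0.0, admin_censor_time=20.0, seed=11,
        )
        coh = generate_cohort(spec)
        curve = conditional_survival(coh, delta=1.0, t_grid=[0.0, 0.5, 1.0, 2.0], horizon=5.0)
        tv = truth(spec, "cs", 0.0, 1.0)
        for i in range(curve.t_grid.size):
            z = (curve.estimate[i] - tv) / curve.se[i]
            assert abs(z) < 3

    def test_undefined_when_survival_hits_zero(self, toy4):
        curve = conditional_survival(toy4, delta=0.0, t_grid=[4.0], horizon=4.0)
        assert curve.undefined_mask[0]


class TestRMRL:
    def test_hand_value(self, toy4):
        curve = rmrl(toy4, delta=2.0, horizon=4.0)
        assert curve.at(1.0) == pytest.approx(2.0, abs=1e-9)

    def test_zero_hazard_gives_delta_with_zero_variance(self):
        coh = Cohort(time=[6.0, 6.0, 6.0], event=[0, 0, 0])
        curve = rmrl(coh, delta=2.0, t_grid=[0.0, 1.0], horizon=6.0)
        np.testing.assert_allclose(curve.estimate, 2.0, atol=1e-9)
        np.testing.assert_allclose(curve.variance, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_bounded_by_delta(self, random_cohorts, seed):
        curve = rmrl(random_cohorts(seed), delta=2.0)
        ok = curve.defined
        assert np.all(curve.estimate[ok] >= -1e-12)
        assert np.all(curve.estimate[ok] <= 2.0 + 1e-9)

    def test_constant_hazard_recovery(self):
        """RMRL = (1 - e^{-lambda*delta}) / lambda for every t."""
        spec = ScenarioSpec(
            n=2000, lambda_cancer=0.25, lambda_other=0.15,
            censoring_rate=0.1, admin_censor_time=20.0, seed=17,
        )
        coh = generate_cohort(spec)
        curve = rmrl(coh, delta=3.0, t_grid=[0.0, 1.0], horizon=6.0)
        tv = truth(spec, "rmrl", 0.0, 3.0)
        for i in range(2):
            assert abs(curve.estimate[i] - tv) < 3 * curve.se[i]


class TestCRMTL:
    def test_worked_interpretation(self):
        """Fifteen-year horizon with 12 expected years lived means 3
        expected years lost."""
        base = PrognosisCurve(
            label="RMRL", delta=15.0,
            t_grid=np.array([2.0]), estimate=np.array([12.0]),
            variance=np.array([0.25]),
            ci_lower=np.array([11.0]), ci_upper=np.array([13.0]),
            undefined_mask=np.array([False]),
        )
        lost = crmtl(base)
        assert lost.estimate[0] == pytest.approx(3.0)
        assert lost.variance[0] == base.variance[0]
        assert lost.ci_lower[0] == pytest.approx(2.0)
        assert lost.ci_upper[0] == pytest.approx(4.0)

    def test_complements_rmrl_pointwise(self, random_cohorts):
        base = rmrl(random_cohorts(5), delta=2.0)
        lost = crmtl(base)
        ok = base.defined
        np.testing.assert_allclose(
            base.estimate[ok] + lost.estimate[ok], 2.0, atol=1e-12
        )
        np.testing.assert_array_equal(base.variance[ok], lost.variance[ok])

    def test_rejects_non_rmrl_curve(self, random_cohorts):
        cs = conditional_survival(random_cohorts(6), delta=1.0)
        with pytest.raises(ValueError):
            crmtl(cs)


class TestCauseSpecific:
    def test_hand_risk_and_proportion(self, toy4):
        risk = cause_specific_curves(toy4, delta=4.0, which="risk", t_grid=[0.0], horizon=4.0)
        prop = cause_specific_curves(toy4, delta=4.0, which="proportion", t_grid=[0.0], horizon=4.0)
        assert risk.estimate[0] == pytest.approx(0.625)
        assert prop.estimate[0] == pytest.approx(0.625)

    def test_symmetric_hazards_give_unit_ratio_zero_difference(self):
        spec = ScenarioSpec(
            n=2000, lambda_cancer=0.2, lambda_other=0.2,
            censoring_rate=0.1, admin_censor_time=20.0, seed=23,
        )
        coh = generate_cohort(spec)
        ratio = cause_specific_curves(coh, 3.0, "ratio", t_grid=[0.0, 1.0], horizon=6.0)
        diff = cause_specific_curves(coh, 3.0, "difference", t_grid=[0.0, 1.0], horizon=6.0)
        for i in range(2):
            assert abs(ratio.estimate[i] - 1.0) < 3 * ratio.se[i]
            assert abs(diff.estimate[i]) < 3 * diff.se[i]

    def test_ratio_recovers_hazard_ratio(self):
        """Under constant cause-specific hazards the risk ratio equals
        lambda_1/lambda_2 at every t."""
        spec = ScenarioSpec(
            n=2000, lambda_cancer=0.3, lambda_other=0.1,
            censoring_rate=0.1, admin_censor_time=20.0, seed=29,
        )
        coh = generate_cohort(spec)
        curve = cause_specific_curves(coh, 5.0, "ratio", t_grid=[0.0, 1.0, 2.0], horizon=8.0)
        for i in range(3):
            assert abs(curve.estimate[i] - 3.0) < 3 * curve.se[i]

    def test_risk_nondecreasing_in_delta(self, random_cohorts):
        coh = random_cohorts(7, n=150)
        t = 0.5
        vals = [
            cause_specific_curves(coh, d, "risk", t_grid=[t]).estimate[0]
            for d in (0.5, 1.0, 2.0, 3.0)
        ]
        assert np.all(np.diff(vals) >= -1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_proportion_in_unit_interval(self, random_cohorts, seed):
        curve = cause_specific_curves(random_cohorts(seed), 2.0, "proportion")
        ok = curve.defined
        assert np.all(curve.estimate[ok] >= -1e-12)
        assert np.all(curve.estimate[ok] <= 1 + 1e-12)

    def test_ratio_undefined_without_other_cause_events(self):
        coh = Cohort(time=[1.0, 2.0, 3.0], event=[1, 1, 0])
        curve = cause_specific_curves(coh, 1.0, "ratio", t_grid=[0.0], horizon=3.0)
        assert curve.undefined_mask[0]

    def test_unknown_kind_rejected(self, toy4):
        with pytest.raises(ValueError):
            cause_specific_curves(toy4, 1.0, "oddsratio")


class TestClosedFormAgreement:
    """The module's central correctness property: the generic engine and
    the printed closed-form variance expressions agree on every cohort.
    The agreement is asserted inside the curve constructors (to 1e-10);
    these tests exercise that path across a corpus of random cohorts and
    parameters."""

    @pytest.mark.parametrize("seed", range(10))
    def test_all_parameters_on_random_cohorts(self, random_cohorts, seed):
        coh = random_cohorts(seed)
        horizon = float(coh.time.max())
        delta = min(2.0, horizon / 2)
        conditional_survival(coh, delta)
        rmrl(coh, delta, mesh_step=0.05)
        for which in ("risk", "ratio", "difference", "proportion"):
            cause_specific_curves(coh, delta, which)


class TestCurveInvariantsAndIO:
    def test_ci_brackets_estimate(self, random_cohorts):
        for curve in (
            conditional_survival(random_cohorts(3), 1.0),
            rmrl(random_cohorts(3), 1.0, mesh_step=0.05),
        ):
            ok = curve.defined
            assert np.all(curve.ci_lower[ok] <= curve.estimate[ok] + 1e-12)
            assert np.all(curve.estimate[ok] <= curve.ci_upper[ok] + 1e-12)
            assert np.all(curve.variance[ok] >= 0)

    @pytest.mark.parametrize("scale", ["plain", "log", "loglog"])
    def test_ci_scales(self, random_cohorts, scale):
        curve = conditional_survival(random_cohorts(4), 1.0, ci_scale=scale)
        ok = curve.defined & (curve.estimate > 0) & (curve.estimate < 1)
        assert np.all(curve.ci_lower[ok] <= curve.estimate[ok] + 1e-12)
        assert np.all(curve.ci_upper[ok] >= curve.estimate[ok] - 1e-12)

    def test_write_read_round_trip(self, random_cohorts, tmp_path):
        curve = conditional_survival(random_cohorts(8), 1.5)
        path = tmp_path / "cs.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        np.testing.assert_array_equal(back.t_grid, curve.t_grid)
        np.testing.assert_array_equal(back.estimate[back.defined], curve.estimate[curve.defined])
        np.testing.assert_array_equal(back.undefined_mask, curve.undefined_mask)
        assert back.label == curve.label and back.delta == curve.delta


class TestCoverage:
    def test_wald_coverage_cs_rmrl_risk(self):
        """Empirical 95% coverage for conditional survival, RMRL, and the
        cause-specific risk lies in [0.93, 0.97] (n = 300, 300 seeded
        replicates here; the acceptance suite runs the full 1000)."""
        t, d = 1.0, 2.0
        base = ScenarioSpec(lambda_cancer=0.3, lambda_other=0.1)
        truths = {p: truth(base, p, t, d) for p in ("cs", "rmrl", "risk")}
        hits = {p: 0 for p in truths}
        reps = 300
        for r in range(reps):
            spec = ScenarioSpec(
                n=300, lambda_cancer=0.3, lambda_other=0.1,
                censoring_rate=0.1, admin_censor_time=10.0, seed=90_000 + r,
            )
            coh = generate_cohort(spec)
            curves = {
                "cs": conditional_survival(coh, d, t_grid=[t], horizon=t + d + 0.1),
                "rmrl": rmrl(coh, d, t_grid=[t], horizon=t + d + 0.1),
                "risk": cause_specific_curves(coh, d, "risk", t_grid=[t], horizon=t + d + 0.1),
            }
            for p, c in curves.items():
                hits[p] += c.ci_lower[0] <= truths[p] <= c.ci_upper[0]
        for p in truths:
            assert 0.92 <= hits[p] / reps <= 0.98, (p, hits[p] / reps)
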
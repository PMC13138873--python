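import numpy as np
import pytest
from scipy import stats

from isapk import virtual_tdm as vt
from isapk.datatypes import PopulationModel


class TestSimulateCohort:
    def test_degenerate_cohort_is_typical_profile(self, final_model):
        pop = final_model.copy(omega_cl=0.0, omega_v=0.0)
        cohort = vt.simulate_cohort(n=50, pop=pop, bmi_range=(25.0, 25.0),
                                    seed=1)
        assert np.allclose(cohort.cl, pop.tvcl)
        assert np.allclose(cohort.v, pop.tvv)
        assert np.allclose(cohort.ipred_true_cmin,
                           cohort.ipred_true_cmin[0])
        assert np.allclose(cohort.auc_true, 200.0 / pop.tvcl)

    def test_half_lives_respect_bounds(self, final_model):
        cohort = vt.simulate_cohort(n=2000, pop=final_model,
                                    half_life_bounds=(60.0, 250.0), seed=2)
        assert cohort.half_life.min() >= 60.0
        assert cohort.half_life.max() <= 250.0

    def test_implausible_bounds_rejected(self, final_model):
        with pytest.raises(ValueError, match="rejection|bounds"):
            vt.simulate_cohort(n=500, pop=final_model,
                               half_life_bounds=(1.0, 2.0), seed=3)

    def test_noisy_trough_positive(self, final_model):
        cohort = vt.simulate_cohort(n=5000, pop=final_model, seed=4)
        assert (cohort.cmin_ruv > 0).all()

    def test_patient_view_matches_arrays(self, final_model):
        cohort = vt.simulate_cohort(n=10, pop=final_model, seed=5)
        p = cohort[3]
        assert p.cl == cohort.cl[3]
        assert p.cmin_ruv == cohort.cmin_ruv[3]
        assert len(cohort) == 10


class TestAttainment:
    def test_inclusive_membership_counting(self, final_model):
        cohort = vt.simulate_cohort(n=4, pop=final_model, seed=1)
        cohort.ipred_true_cmin = np.array([2.0, 2.5, 3.0, 6.0])
        cohort.auc_true = np.array([50.0, 60.0, 100.0, 250.0])
        s = vt.attainment(cohort)
        assert s.pct_cmin_in_range == pytest.approx(50.0)
        assert s.pct_auc_in_range == pytest.approx(50.0)
        assert s.n == 4

    def test_invalid_range_rejected(self, final_model):
        cohort = vt.simulate_cohort(n=4, pop=final_model, seed=1)
        with pytest.raises(ValueError):
            vt.attainment(cohort, cmin_range=(5.0, 2.5))

    def test_analytic_lognormal_cross_check(self, final_model):
        """No-TDM trough attainment vs numeric lognormal-theory integral.

        Integrates P(2.5 <= cmin(eta_cl, eta_v, bmi) <= 5) over the
        generative distributions with the half-life filter disabled.
        """
        pop = final_model
        cohort = vt.simulate_cohort(n=40000, pop=pop,
                                    half_life_bounds=(1.0, 1e7), seed=6)
        sim_pct = vt.attainment(cohort).pct_cmin_in_range

        from isapk.pk_core import cmin_ss_batch
        nq = 61
        z, w = np.polynomial.hermite_e.hermegauss(nq)
        bmis = np.linspace(12.0, 40.0, 41)
        prob = 0.0
        wsum = 0.0
        for b in bmis:
            ec = (z * pop.omega_cl)[:, None]
            ev = (z * pop.omega_v)[None, :]
            cl = pop.tvcl * np.exp(ec) * np.ones_like(ev)
            v = pop.tvv * (b / 25.0) * np.exp(ev) * np.ones_like(ec)
            c = cmin_ss_batch(200.0, 24.0, cl.ravel(), v.ravel(), pop.ka)
            inside = ((c >= 2.5) & (c <= 5.0)).reshape(nq, nq)
            ww = w[:, None] * w[None, :]
            prob += (ww * inside).sum()
            wsum += ww.sum()
        theory_pct = 100.0 * prob / wsum
        assert sim_pct == pytest.approx(theory_pct, abs=2.0)


class TestDoseAdjustment:
    @pytest.mark.parametrize("current,observed,target,expected", [
        (200.0, 1.77, 3.5355, 400.0),    # ideal ~399.5 -> nearest 400
        (200.0, 3.5355, 3.5355, 200.0),  # on target: unchanged
        (200.0, 14.0, 3.5355, 100.0),    # ideal ~50.5 -> lowest dose
        (100.0, 2.0, 3.0, 100.0),        # ideal 150: midpoint tie -> lower
    ])
    def test_proportional_rule(self, current, observed, target, expected):
        assert vt.adjust_dose_proportional(current, observed, target) == \
            expected

    def test_vectorized_matches_scalar(self, rng):
        obs = rng.uniform(0.5, 12.0, 50)
        vec = vt.adjust_dose_proportional(200.0, obs, 3.5355)
        scalar = [vt.adjust_dose_proportional(200.0, o, 3.5355) for o in obs]
        assert np.array_equal(vec, scalar)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(ValueError):
            vt.adjust_dose_proportional(200.0, 0.0, 3.5)


class TestApplyStrategy:
    @pytest.fixture(scope="class")
    def cohort(self, final_model):
        return vt.simulate_cohort(n=4000, pop=final_model, seed=8)

    def test_none_strategy_is_identity(self, cohort, final_model):
        adjusted, summary = vt.apply_strategy(
            cohort, vt.TdmStrategy(kind="none"), final_model)
        base = vt.attainment(cohort)
        assert summary.pct_cmin_in_range == base.pct_cmin_in_range
        assert np.array_equal(adjusted.dose, cohort.dose)

    def test_unknown_strategy_rejected(self, cohort, final_model):
        with pytest.raises(ValueError):
            vt.apply_strategy(cohort, vt.TdmStrategy(kind="magic"),
                              final_model)

    def test_adjusted_doses_on_allowed_grid(self, cohort, final_model):
        for kind in ("proportional_cmin", "mipd_cmin", "mipd_auc"):
            strategy = vt.TdmStrategy(
                kind=kind, target_range=(vt.AUC_TARGET_RANGE
                                         if kind == "mipd_auc"
                                         else vt.CMIN_TARGET_RANGE))
            adjusted, _ = vt.apply_strategy(cohort, strategy, final_model)
            assert set(np.unique(adjusted.dose)) <= set(vt.ALLOWED_DOSES)

    def test_trough_strategies_do_not_reduce_attainment(self, cohort,
                                                        final_model):
        base = vt.attainment(cohort).pct_cmin_in_range
        for kind in ("proportional_cmin", "mipd_cmin"):
            _, s = vt.apply_strategy(cohort, vt.TdmStrategy(kind=kind),
                                     final_model)
            assert s.pct_cmin_in_range >= base - 1.5  # Monte-Carlo slack

    def test_noise_free_mipd_equals_proportional(self, final_model):
        """With no residual error the Bayes trough equals the observed one,
        so both strategies make identical dose decisions."""
        pop = final_model.copy(sigma_prop=1e-3, sigma_add=1e-3)
        cohort = vt.simulate_cohort(n=500, pop=pop, seed=9)
        a1, _ = vt.apply_strategy(cohort,
                                  vt.TdmStrategy(kind="proportional_cmin"),
                                  pop)
        a2, _ = vt.apply_strategy(cohort, vt.TdmStrategy(kind="mipd_cmin"),
                                  pop)
        assert np.array_equal(a1.dose, a2.dose)

    def test_on_target_measurement_keeps_dose(self, cohort, final_model):
        modified = vt.VirtualCohort(**{
            f: getattr(cohort, f).copy() for f in (
                "bmi", "cl", "v", "half_life", "dose",
                "ipred_true_cmin", "auc_true", "cmin_ruv")})
        strategy = vt.TdmStrategy(kind="proportional_cmin")
        modified.cmin_ruv[:] = strategy.target_value
        adjusted, _ = vt.apply_strategy(modified, strategy, final_model)
        assert np.array_equal(adjusted.dose, modified.dose)

    def test_strategy_target_value_is_geometric_mean(self):
        s = vt.TdmStrategy(kind="proportional_cmin")
        assert s.target_value == pytest.approx(np.sqrt(2.5 * 5.0))
        s2 = vt.TdmStrategy(kind="mipd_auc", target_range=(60.0, 233.0))
        assert s2.target_value == pytest.approx(np.sqrt(60.0 * 233.0))
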
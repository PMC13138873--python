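import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isapk import pk_core, poppk_fit
from isapk.datatypes import (
    DoseEvent,
    IndividualParameters,
    Observation,
    PopulationModel,
    SubjectRecord,
)
from .conftest import make_qd_subject


def qd_subject_with_noise(sid, pop, eta_cl, eta_v, rng, n_obs=5,
                          dose=200.0, bmi=25.0):
    ind = pk_core.individual_parameters(pop, bmi, eta_cl, eta_v)
    doses = [DoseEvent(time=24.0 * k, amount=dose) for k in range(20)]
    obs = []
    tads = rng.uniform(1.0, 24.0, n_obs)
    for j, tad in enumerate(tads):
        t = 24.0 * (12 + j % 6) + tad
        f = pk_core.concentration(t, doses, ind)
        y = -1.0
        while y <= 0:
            y = f * (1 + rng.normal(0, pop.sigma_prop)) \
                + rng.normal(0, pop.sigma_add)
        obs.append(Observation(time=t, value=y))
    return SubjectRecord(subject_id=sid, doses=doses, observations=obs)


class TestMarginalNeg2ll:
    def test_zero_omega_equals_fixed_eta_gaussian(self, final_model):
        pop = final_model.copy(omega_cl=0.0, omega_v=0.0)
        s = make_qd_subject(obs_spec=[(300.0, 3.0), (350.0, 2.5)])
        ofv = poppk_fit.marginal_neg2ll([s], pop)
        ind = IndividualParameters(cl=pop.tvcl, v=pop.tvv, ka=pop.ka)
        expected = 0.0
        for o in s.observations:
            f = pk_core.concentration(o.time, s.doses, ind)
            var = (f * pop.sigma_prop) ** 2 + pop.sigma_add ** 2
            expected += math.log(2 * math.pi * var) + (o.value - f) ** 2 / var
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_duplicating_subjects_doubles_ofv(self, final_model, rng):
        subs = [qd_subject_with_noise(f"A{i}", final_model, 0.2, -0.1, rng)
                for i in range(3)]
        one = poppk_fit.marginal_neg2ll(subs, final_model)
        twice = poppk_fit.marginal_neg2ll(
            subs + [SubjectRecord(subject_id=s.subject_id + "b",
                                  doses=s.doses,
                                  observations=s.observations)
                    for s in subs], final_model)
        assert twice == pytest.approx(2 * one, rel=1e-8)

    def test_single_subject_laplace_close_to_quadrature(self, final_model, rng):
        """AGQ-refined marginal within 0.1% of 2-D adaptive integration."""
        from scipy import integrate

        s = qd_subject_with_noise("Q1", final_model, 0.3, 0.1, rng, n_obs=1)
        ofv = poppk_fit.marginal_neg2ll([s], final_model, agq_nodes=9)
        obs = [(o.time, o.value) for o in s.observations]
        pop = final_model

        def integrand(ev, ec):
            ind = IndividualParameters(cl=pop.tvcl * np.exp(ec),
                                       v=pop.tvv * np.exp(ev), ka=pop.ka)
            ll = 1.0
            for t, y in obs:
                f = pk_core.concentration(t, s.doses, ind)
                var = (f * pop.sigma_prop) ** 2 + pop.sigma_add ** 2
                ll *= math.exp(-0.5 * (y - f) ** 2 / var) / math.sqrt(
                    2 * math.pi * var)
            pri = (math.exp(-0.5 * (ec / pop.omega_cl) ** 2)
                   / (math.sqrt(2 * math.pi) * pop.omega_cl)
                   * math.exp(-0.5 * (ev / pop.omega_v) ** 2)
                   / (math.sqrt(2 * math.pi) * pop.omega_v))
            return ll * pri

        val, _ = integrate.dblquad(
            integrand, -8 * pop.omega_cl, 8 * pop.omega_cl,
            -8 * pop.omega_v, 8 * pop.omega_v, epsabs=1e-12, epsrel=1e-9)
        assert ofv == pytest.approx(-2 * math.log(val), rel=1e-3)


class TestFit:
    def test_fully_masked_fit_returns_start(self, final_model, rng):
        subs = [qd_subject_with_noise(f"M{i}", final_model, 0.0, 0.0, rng)
                for i in range(3)]
        res = poppk_fit.fit(subs, final_model,
                            fixed={"tvcl", "tvv", "ka", "f_oral", "omega_cl",
                                   "omega_v", "sigma_prop", "sigma_add"})
        assert res.estimates.tvcl == final_model.tvcl
        assert res.ofv == pytest.approx(
            poppk_fit.marginal_neg2ll(subs, final_model), rel=1e-9)
        assert res.n_params == 0

    def test_refit_does_not_beat_truth_by_much(self, rich_cohort, final_model):
        """Self-simulated data: fitted OFV <= truth OFV + tiny slack."""
        subjects, _ = rich_cohort
        res = poppk_fit.fit(subjects, final_model, n_starts=1,
                            compute_rse=False, maxfev=1500)
        truth_ofv = poppk_fit.marginal_neg2ll(subjects, final_model)
        assert res.ofv <= truth_ofv + 1e-6

    def test_rse_reported_for_free_parameters(self, rich_cohort, final_model):
        subjects, _ = rich_cohort
        res = poppk_fit.fit(subjects[:30], final_model, n_starts=1,
                            maxfev=600)
        assert set(res.rse) == {"tvcl", "tvv", "omega_cl", "omega_v",
                                "sigma_prop", "sigma_add"}
        assert res.rse["tvcl"] > 0


class TestComparisons:
    def _fake_fit(self, ofv, k):
        return poppk_fit.FitResult(
            ofv=ofv, estimates=PopulationModel(), theta={}, rse={},
            ebes=np.zeros((1, 2)), subject_ids=["x"],
            cwres=pd.DataFrame(), shrinkage={}, converged=True, n_params=k)

    @pytest.mark.parametrize("delta,mode,decision", [
        (-11.0, "forward", "accept_complex"),
        (-3.84, "forward", "accept_complex"),   # inclusive boundary
        (-2.0, "forward", "keep_simple"),
        (-6.64, "backward", "accept_complex"),
        (-6.0, "backward", "keep_simple"),
    ])
    def test_lrt_thresholds(self, delta, mode, decision):
        simple = self._fake_fit(100.0, 3)
        complex_ = self._fake_fit(100.0 + delta, 4)
        res = poppk_fit.lrt_compare(simple, complex_, alpha_mode=mode)
        assert res.decision == decision
        assert 0.0 <= res.p_value <= 1.0

    def test_lrt_needs_extra_parameters(self):
        with pytest.raises(ValueError):
            poppk_fit.lrt_compare(self._fake_fit(10, 3), self._fake_fit(9, 3))

    @pytest.mark.parametrize("ofv_b,k_b,decision", [
        (98.0, 3, "accept_complex"),    # dAIC = -2.0
        (98.1, 3, "keep_simple"),       # dAIC = -1.9
        (100.0, 3, "keep_simple"),      # equal AIC
    ])
    def test_aic_rule(self, ofv_b, k_b, decision):
        a = self._fake_fit(100.0, 3)
        b = self._fake_fit(ofv_b, k_b)
        assert poppk_fit.aic_compare(a, b).decision == decision


class TestCwres:
    def test_outlier_flagged(self, final_model, rng):
        s = qd_subject_with_noise("O1", final_model, 0.0, 0.0, rng, n_obs=6)
        # corrupt one observation to 10x its value
        obs = list(s.observations)
        bad = Observation(time=obs[3].time, value=obs[3].value * 10)
        obs[3] = bad
        s2 = SubjectRecord(subject_id="O1", doses=s.doses, observations=obs)
        ofv, eta = poppk_fit.marginal_neg2ll([s2], final_model,
                                             return_etas=True)
        cw = poppk_fit.compute_cwres(poppk_fit.Design([s2]), final_model, eta)
        flagged = cw[np.abs(cw["cwres"]) > 3]
        assert bad.time in set(flagged["time"])

    def test_infinite_threshold_flags_nothing(self, final_model, rng):
        s = qd_subject_with_noise("O2", final_model, 0.0, 0.0, rng)
        res = poppk_fit.fit([s], final_model, fixed={
            "tvcl", "tvv", "ka", "f_oral", "omega_cl", "omega_v",
            "sigma_prop", "sigma_add"})
        assert poppk_fit.cwres_flag(res, threshold=np.inf).empty


class TestShrinkage:
    @pytest.mark.parametrize("ebes,omega,expected", [
        (np.array([0.3, -0.3]), 0.3, 0.0),
        (np.zeros(5), 0.4, 100.0),
        (np.array([0.2, -0.2]), 0.4, 50.0),
    ])
    def test_definition(self, ebes, omega, expected):
        assert poppk_fit.eta_shrinkage(ebes, omega) == pytest.approx(expected)


class TestBootstrap:
    def test_identical_subjects_reproduce_fit(self, final_model, rng):
        base = qd_subject_with_noise("B", final_model, 0.1, 0.0, rng, n_obs=6)
        subs = [SubjectRecord(subject_id=f"B{i}", doses=base.doses,
                              observations=base.observations)
                for i in range(3)]
        start = final_model
        ref = poppk_fit.fit(subs, start, n_starts=1, compute_rse=False,
                            maxfev=400)
        boot = poppk_fit.bootstrap(subs, start, n=1, seed=5, maxfev=400)
        # resampling identical subjects yields the identical dataset
        for nm in ref.theta:
            assert boot.replicates[nm].iloc[0] == pytest.approx(
                ref.theta[nm], rel=5e-2)

    def test_ci_ordering(self, rich_cohort, final_model):
        subjects, _ = rich_cohort
        boot = poppk_fit.bootstrap(subjects[:12], final_model, n=8, seed=3,
                                   maxfev=300)
        s = boot.summary
        assert (s["ci_low"] <= s["median"]).all()
        assert (s["median"] <= s["ci_high"]).all()
        assert boot.n_replicates == 8


class TestStepwise:
    def test_empty_candidate_list_returns_base(self, rich_cohort, final_model):
        subjects, _ = rich_cohort
        base = poppk_fit.fit(subjects[:15], final_model, n_starts=1,
                             compute_rse=False, maxfev=400)
        final, trace, iiv = poppk_fit.stepwise_covariates(
            subjects[:15], base, [])
        assert final is base
        assert trace.empty and iiv == {}

    def test_all_missing_covariate_skipped(self, rich_cohort, final_model):
        subjects, _ = rich_cohort
        base = poppk_fit.fit(subjects[:10], final_model, n_starts=1,
                             compute_rse=False, maxfev=300)
        cand = poppk_fit.CovariateCandidate("cl", "egfr", poppk_fit.POWER)
        # erase the covariate everywhere
        stripped = []
        for s in subjects[:10]:
            recs = [type(r)(**{**vars(r), "egfr": None})
                    for r in s.covariates]
            stripped.append(SubjectRecord(
                subject_id=s.subject_id, doses=s.doses,
                observations=s.observations, covariates=recs))
        with pytest.warns(UserWarning, match="egfr"):
            final, trace, _ = poppk_fit.stepwise_covariates(
                stripped, base, [cand])
        assert trace.empty
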
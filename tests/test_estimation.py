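"""Estimation engine: objective oracles, EBEs, recovery, stepwise screening."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neopk import (
    Covariates,
    CovariateEffect,
    CovariateModelSpec,
    DoseEvent,
    Observation,
    PKDataset,
    PopModelParams,
    SubjectRecord,
    concentration,
    cv_percent,
    cv_to_omega2,
    empirical_bayes,
    fit_population,
    foce_objective,
    generate_study,
    handle_blq,
    individual_clearance,
    individual_volume,
    stepwise_covariate_selection,
)
from neopk.estimation import shrinkage
from neopk.pkmodel import IndividualParams
from neopk.synth import StudyDesignConfig

from conftest import make_subject


def small_dataset(seed=11, n=5, rich=False):
    truth = PopModelParams(tvcl=19.6, tvv=70.6, omega2_cl=0.076,
                           omega2_v=0.165, sigma2=0.0485)
    cfg = StudyDesignConfig(n_subjects=n)
    if rich:
        # four samples per subject: the rich end of the design support
        cfg = StudyDesignConfig(n_subjects=n,
                                samples_per_subject_probs=(0.0, 0.0, 0.0, 1.0))
    ds, _ = generate_study(truth, cfg, seed=seed)
    return handle_blq(ds), truth


def quadrature_ofv(ds, params):
    """Independent oracle: -2 log marginal likelihood by dense 2-D
    quadrature of the exact integrand over a wide eta grid."""
    om = np.array([params.omega2_cl, params.omega2_v])
    s2 = params.sigma2
    lim = 6.0 * np.sqrt(om)
    g1 = np.linspace(-lim[0], lim[0], 301)
    g2 = np.linspace(-lim[1], lim[1], 301)
    E1, E2 = np.meshgrid(g1, g2, indexing="ij")
    total = 0.0
    for s in ds.subjects:
        cl0 = individual_clearance(params, s.covariates)
        v0 = individual_volume(params, s.covariates)
        loglik = np.zeros_like(E1)
        for o in s.observations:
            f = np.empty_like(E1)
            for i in range(E1.shape[0]):
                ind = None
                cl = cl0 * np.exp(E1[i, 0])
                f[i, :] = [
                    concentration(o.time,
                                  IndividualParams(cl=cl, v=v0 * np.exp(e2)),
                                  s.doses)
                    for e2 in g2
                ]
            r = np.log(o.conc) - np.log(f)
            loglik += -0.5 * (np.log(2 * np.pi * s2) + r * r / s2)
        prior = (
            -0.5 * (np.log(2 * np.pi * om[0]) + E1 * E1 / om[0])
            - 0.5 * (np.log(2 * np.pi * om[1]) + E2 * E2 / om[1])
        )
        integrand = np.exp(loglik + prior)
        L = np.trapezoid(np.trapezoid(integrand, g2, axis=1), g1)
        total += -2.0 * np.log(L)
    return total


class TestObjective:
    def test_degenerate_variances_reduce_to_residual_sum(self, ref_params):
        ds, truth = small_dataset()
        p = PopModelParams(tvcl=truth.tvcl, tvv=truth.tvv, omega2_cl=0.0,
                           omega2_v=0.0, sigma2=truth.sigma2)
        ofv = foce_objective(ds, p)
        expected = 0.0
        for s in ds.subjects:
            cl = individual_clearance(p, s.covariates)
            v = individual_volume(p, s.covariates)
            for o in s.observations:
                pred = concentration(o.time, IndividualParams(cl=cl, v=v), s.doses)
                r = np.log(o.conc) - np.log(pred)
                expected += np.log(2 * np.pi * p.sigma2) + r * r / p.sigma2
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_additive_over_subjects(self):
        ds, truth = small_dataset()
        single = PKDataset(subjects=(ds.subjects[0],))
        dup_subject = SubjectRecord("DUP", ds.subjects[0].covariates,
                                    ds.subjects[0].doses, ds.subjects[0].observations)
        dup = PKDataset(subjects=ds.subjects + (dup_subject,))
        assert foce_objective(dup, truth) == pytest.approx(
            foce_objective(ds, truth) + foce_objective(single, truth), rel=1e-10
        )

    def test_within_one_percent_of_quadrature(self):
        # four observations per subject keep the conditional posteriors
        # close enough to Gaussian for the Laplace expansion to track the
        # exact marginal likelihood at the 1% level
        ds, truth = small_dataset(seed=11, n=5, rich=True)
        ofv = foce_objective(ds, truth)
        oracle = quadrature_ofv(ds, truth)
        assert ofv == pytest.approx(oracle, rel=0.01)

    def test_invariant_to_subject_ordering(self):
        ds, truth = small_dataset(n=8)
        perm = PKDataset(subjects=tuple(reversed(ds.subjects)))
        assert foce_objective(perm, truth) == pytest.approx(
            foce_objective(ds, truth), rel=1e-12
        )

    def test_unit_invariance_hours_to_minutes(self):
        ds, truth = small_dataset(n=6)
        subs_min = []
        for s in ds.subjects:
            doses = tuple(DoseEvent(d.time * 60, d.amount, d.infusion_duration * 60)
                          for d in s.doses)
            obs = tuple(Observation(o.time * 60, o.conc, o.blq_flag)
                        for o in s.observations)
            subs_min.append(SubjectRecord(s.subject_id, s.covariates, doses, obs))
        ds_min = PKDataset(subjects=tuple(subs_min))
        p_min = PopModelParams(tvcl=truth.tvcl / 60, tvv=truth.tvv,
                               omega2_cl=truth.omega2_cl, omega2_v=truth.omega2_v,
                               sigma2=truth.sigma2)
        assert foce_objective(ds_min, p_min) == pytest.approx(
            foce_objective(ds, truth), rel=1e-9
        )

    def test_compiled_and_reference_paths_agree(self):
        ds, truth = small_dataset(n=10)
        a = foce_objective(ds, truth, compiled=True)
        b = foce_objective(ds, truth, compiled=False)
        assert a == pytest.approx(b, abs=1e-8)


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self, ref_params):
        s = make_subject(obs=())
        assert empirical_bayes(s, ref_params) == (0.0, 0.0)

    def test_data_at_typical_predictions_gives_near_zero_etas(self, ref_params):
        cov = Covariates(wt=3.2, pma=39.4, ga=39.0, pna=2.0, scr=56.7)
        cl = individual_clearance(ref_params, cov)
        v = individual_volume(ref_params, cov)
        doses = (DoseEvent(0.0, 80.0, 0.5),)
        times = (0.4, 2.5, 5.0)
        obs = tuple(
            Observation(t, float(concentration(t, IndividualParams(cl=cl, v=v), doses)))
            for t in times
        )
        s = SubjectRecord("T", cov, doses, obs)
        p = PopModelParams(tvcl=ref_params.tvcl, tvv=ref_params.tvv,
                           omega2_cl=0.076, omega2_v=0.165, sigma2=1e-8)
        eta = empirical_bayes(s, p)
        assert abs(eta[0]) < 1e-4 and abs(eta[1]) < 1e-4

    def test_matches_grid_search_map(self, ref_params):
        ds, truth = small_dataset(n=3)
        s = ds.subjects[0]
        eta = empirical_bayes(s, truth)
        cl0 = individual_clearance(truth, s.covariates)
        v0 = individual_volume(truth, s.covariates)

        def neg_post(e1, e2):
            q = e1 * e1 / truth.omega2_cl + e2 * e2 / truth.omega2_v
            for o in s.observations:
                f = concentration(
                    o.time, IndividualParams(cl=cl0 * np.exp(e1), v=v0 * np.exp(e2)),
                    s.doses)
                r = np.log(o.conc) - np.log(f)
                q += r * r / truth.sigma2
            return q

        # two-stage dense grid search around the prior
        best = (0.0, 0.0)
        for span, num in ((1.5, 121), (0.05, 201)):
            g1 = np.linspace(best[0] - span, best[0] + span, num)
            g2 = np.linspace(best[1] - span, best[1] + span, num)
            vals = np.array([[neg_post(a, b) for b in g2] for a in g1])
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            best = (g1[i], g2[j])
        assert abs(eta[0] - best[0]) < 1e-3
        assert abs(eta[1] - best[1]) < 1e-3


class TestVarianceReporting:
    def test_cv_zero(self):
        assert cv_percent(0.0) == 0.0

    def test_cv_of_reported_iiv(self):
        # omega2 = 0.0760 corresponds to the published 28.1 CV%
        assert cv_percent(0.0760) == pytest.approx(28.1, abs=0.05)

    def test_cv_ln2_is_100(self):
        assert cv_percent(np.log(2.0)) == pytest.approx(100.0, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(cv=st.floats(0.01, 300.0))
    def test_cv_round_trip(self, cv):
        assert cv_percent(cv_to_omega2(cv)) == pytest.approx(cv, abs=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(-0.1)
        with pytest.raises(ValueError):
            cv_to_omega2(-1.0)

    def test_shrinkage_degenerate_cases(self, ref_params):
        from neopk.estimation import FitResult
        ebes = np.zeros((10, 2))
        fit = FitResult(ref_params, 0.0, ebes, None, None, None, True, False)
        s_cl, s_v, _ = shrinkage(fit, ref_params)
        assert s_cl == pytest.approx(100.0)
        rng = np.random.default_rng(0)
        draw = rng.normal(0, 1.0, size=500)
        ebes = np.column_stack([
            draw / draw.std(ddof=1) * np.sqrt(ref_params.omega2_cl),
            draw / draw.std(ddof=1) * np.sqrt(ref_params.omega2_v),
        ])
        fit = FitResult(ref_params, 0.0, ebes, None, None, None, True, False)
        s_cl, s_v, _ = shrinkage(fit, ref_params)
        assert s_cl == pytest.approx(0.0, abs=1e-9)
        assert s_v == pytest.approx(0.0, abs=1e-9)

    def test_rich_data_shrinkage_is_low(self):
        truth = PopModelParams(tvcl=19.6, tvv=70.6, omega2_cl=0.076,
                               omega2_v=0.165, sigma2=0.0485)
        # 9 samples per subject (3 per window) is a rich design
        cfg = StudyDesignConfig(
            n_subjects=40,
            samples_per_subject_probs=(0.0, 0.0, 0.0, 1.0),
        )
        ds, _ = generate_study(truth, cfg, seed=21)
        fit = fit_population(handle_blq(ds), truth)
        assert fit.eta_shrinkage_cl < 25.0
        assert fit.eta_shrinkage_v < 25.0


class TestFit:
    def test_noise_free_identifiability(self):
        truth = PopModelParams(tvcl=19.6, tvv=70.6, omega2_cl=0.0,
                               omega2_v=0.0, sigma2=1e-12)
        cfg = StudyDesignConfig(n_subjects=20,
                                samples_per_subject_probs=(0.0, 0.0, 0.0, 1.0))
        ds, _ = generate_study(truth, cfg, seed=5)
        init = PopModelParams(tvcl=15.0, tvv=50.0, omega2_cl=1e-6,
                              omega2_v=1e-6, sigma2=1e-6)
        fit = fit_population(ds, init)
        assert fit.params.tvcl == pytest.approx(19.6, rel=1e-4)
        assert fit.params.tvv == pytest.approx(70.6, rel=1e-4)
        assert fit.boundary  # variances collapse by construction

    def test_fit_is_deterministic(self):
        ds, truth = small_dataset(n=12, seed=3)
        f1 = fit_population(ds, truth)
        f2 = fit_population(ds, truth)
        assert f1.ofv == f2.ofv
        assert f1.params == f2.params


class TestStepwise:
    def test_empty_candidate_list_returns_base(self):
        ds, truth = small_dataset(n=8)
        base = fit_population(ds, truth)
        sel = stepwise_covariate_selection(ds, base, CovariateModelSpec())
        assert sel.terms == ()
        assert sel.fit is base

    def test_strong_covariate_is_selected(self):
        # clearance truly scales with (SCR/56.7)^-1.0; the screen must find it
        truth = PopModelParams(tvcl=19.6, tvv=70.6, omega2_cl=0.02,
                               omega2_v=0.05, sigma2=0.02)
        cfg = StudyDesignConfig(n_subjects=48)
        rng = np.random.default_rng(77)
        base_ds, gt = generate_study(truth, cfg, seed=77)
        subjects = []
        for s in base_ds.subjects:
            shift = -1.0 * np.log(s.covariates.scr / 56.7)
            obs = []
            cl = individual_clearance(truth, s.covariates) * np.exp(shift)
            # rebuild observations at the covariate-shifted clearance
            for o in s.observations:
                ind = IndividualParams(cl=cl, v=individual_volume(truth, s.covariates))
                c = float(concentration(o.time, ind, s.doses))
                c *= np.exp(rng.normal(0, np.sqrt(truth.sigma2)))
                obs.append(Observation(o.time, c, blq_flag=c < 0.25))
            subjects.append(SubjectRecord(s.subject_id, s.covariates, s.doses,
                                          tuple(obs)))
        ds = handle_blq(PKDataset(subjects=tuple(subjects)))
        base = fit_population(ds, truth)
        cand = CovariateEffect("scr", on="cl", form="power", reference=56.7)
        spec = CovariateModelSpec(candidates=(cand,))
        sel = stepwise_covariate_selection(ds, base, spec)
        assert cand in sel.terms
        theta = sel.fit.thetas[sel.fit.covariate_terms.index(cand)]
        assert theta == pytest.approx(-1.0, abs=0.35)
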
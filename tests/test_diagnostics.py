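"""Diagnostics: residual tables, VPC calibration machinery, bootstrap."""
import numpy as np
import pytest

from neopk import (
    Covariates,
    DoseEvent,
    Observation,
    PKDataset,
    PopModelParams,
    SubjectRecord,
    bootstrap,
    concentration,
    foce_objective,
    generate_study,
    gof_table,
    handle_blq,
    individual_clearance,
    individual_volume,
    vpc,
)
from neopk.estimation import FitResult
from neopk.pkmodel import IndividualParams
from neopk.synth import StudyDesignConfig


def fit_at_truth(ds, truth):
    """A FitResult holding the true parameters with freshly computed EBEs."""
    ofv, ebes = foce_objective(ds, truth, return_ebes=True)
    return FitResult(params=truth, ofv=ofv, ebes=ebes, eta_shrinkage_cl=None,
                     eta_shrinkage_v=None, eps_shrinkage=None, converged=True,
                     boundary=False)


@pytest.fixture(scope="module")
def study(ref_params):
    ds, _ = generate_study(ref_params, seed=31)
    return handle_blq(ds)


class TestGofTable:
    def test_row_count_matches_observations(self, study, ref_params):
        g = gof_table(study, fit_at_truth(study, ref_params))
        assert len(g) == study.n_observations

    def test_iwres_zero_for_noise_free_data(self, ref_params):
        # observations placed exactly at the subject's own curve
        cov = Covariates(wt=3.2, pma=39.4, ga=39.0, pna=2.0, scr=56.7)
        doses = (DoseEvent(0.0, 80.0, 0.5),)
        eta = (0.25, -0.1)
        ind = IndividualParams(
            cl=individual_clearance(ref_params, cov, eta[0]),
            v=individual_volume(ref_params, cov, eta[1]),
        )
        obs = tuple(Observation(t, float(concentration(t, ind, doses)))
                    for t in (0.4, 2.5, 5.0))
        ds = PKDataset(subjects=(SubjectRecord("N", cov, doses, obs),))
        # with a tiny residual variance the conditional modes coincide with
        # the generating etas, so the individual residuals vanish
        from dataclasses import replace
        tight = replace(ref_params, sigma2=1e-10)
        fit = fit_at_truth(ds, tight)
        g = gof_table(ds, fit)
        # EBEs land on the generating etas, so individual residuals vanish
        assert np.allclose(g.iwres, 0.0, atol=1e-3)
        assert np.allclose(g.ipred, g.dv, rtol=1e-4)

    def test_cwres_standard_normal_under_true_model(self, ref_params):
        ds, _ = generate_study(ref_params, seed=13)
        ds = handle_blq(ds)
        g = gof_table(ds, fit_at_truth(ds, ref_params))
        assert abs(g.cwres.mean()) < 0.15
        assert 0.8 < g.cwres.std(ddof=1) < 1.2

    def test_single_observation_zero_omega_reduces_to_standardized_residual(self):
        p = PopModelParams(tvcl=19.6, tvv=70.6, omega2_cl=0.0, omega2_v=0.0,
                           sigma2=0.04)
        cov = Covariates(wt=3.2, pma=39.4, ga=39.0, pna=2.0)
        doses = (DoseEvent(0.0, 80.0, 0.5),)
        obs = (Observation(2.5, 12.0),)
        ds = PKDataset(subjects=(SubjectRecord("A", cov, doses, obs),))
        g = gof_table(ds, fit_at_truth(ds, p))
        pred = float(concentration(2.5, IndividualParams(
            cl=individual_clearance(p, cov), v=individual_volume(p, cov)), doses))
        expected = (np.log(12.0) - np.log(pred)) / np.sqrt(p.sigma2)
        assert g.cwres.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert g.iwres.iloc[0] == pytest.approx(expected, rel=1e-9)


class TestVpc:
    def test_coverage_calibrated_on_self_simulated_data(self, study, ref_params):
        v = vpc(study, ref_params, n_sim=400, seed=17)
        assert v.coverage == pytest.approx(90.0, abs=4.0)

    def test_single_replicate_degenerates_to_its_quantiles(self, study, ref_params):
        v = vpc(study, ref_params, n_sim=1, seed=5)
        assert np.allclose(v.simulated_bands[:, :, 0], v.simulated_quantiles)
        assert np.allclose(v.simulated_bands[:, :, 1], v.simulated_quantiles)

    def test_bands_ordered(self, study, ref_params):
        v = vpc(study, ref_params, n_sim=200, seed=7)
        assert np.all(v.simulated_quantiles[0] <= v.simulated_quantiles[1])
        assert np.all(v.simulated_quantiles[1] <= v.simulated_quantiles[2])
        assert np.all(v.observed_quantiles[0] <= v.observed_quantiles[2])

    def test_bit_reproducible_under_seed(self, study, ref_params):
        a = vpc(study, ref_params, n_sim=50, seed=3)
        b = vpc(study, ref_params, n_sim=50, seed=3)
        assert np.array_equal(a.simulated_quantiles, b.simulated_quantiles)
        assert a.coverage == b.coverage

    def test_empty_bin_merged_with_warning(self, study, ref_params, caplog):
        bins = ((0.0, 0.5), (1.0, 1.5), (2.0, 3.0), (4.0, 6.0))
        with caplog.at_level("WARNING", logger="neopk.diagnostics"):
            v = vpc(study, ref_params, n_sim=20, seed=1, bins=bins)
        # times 1.0-1.5 h are never sampled by the design
        assert len(v.bin_edges) < len(bins)
        assert any("merged" in r.message for r in caplog.records)

    def test_simulated_median_approaches_model_median(self, ref_params):
        # one subject design with a single fixed time; the simulated median
        # must converge to the analytic median concentration exp(log f_typ)
        cov = Covariates(wt=3.2, pma=39.4, ga=39.0, pna=2.0)
        doses = (DoseEvent(0.0, 80.0, 0.5),)
        ds = PKDataset(subjects=tuple(
            SubjectRecord(f"S{i}", cov, doses, (Observation(2.5, 10.0),))
            for i in range(40)
        ))
        v = vpc(ds, ref_params, n_sim=4000, seed=23, bins=((2.0, 3.0),))
        # brute-force oracle for the model's median concentration at t=2.5 h
        rng = np.random.default_rng(99)
        n = 200_000
        cl = individual_clearance(ref_params, cov) * np.exp(
            rng.normal(0, np.sqrt(ref_params.omega2_cl), n))
        vv = individual_volume(ref_params, cov) * np.exp(
            rng.normal(0, np.sqrt(ref_params.omega2_v), n))
        k = cl / vv
        f = (160.0 / cl) * -np.expm1(-k * 0.5) * np.exp(-k * 2.0)
        c = f * np.exp(rng.normal(0, np.sqrt(ref_params.sigma2), n))
        oracle = float(np.median(c))
        assert v.simulated_quantiles[1, 0] == pytest.approx(oracle, rel=0.03)


class TestBootstrap:
    def test_single_replicate_ci_equals_estimate(self, ref_params):
        ds, _ = generate_study(ref_params, StudyDesignConfig(n_subjects=20), seed=41)
        ds = handle_blq(ds)
        b = bootstrap(ds, ref_params, n_replicates=1, seed=9)
        s = b.summary.loc["tvcl"]
        assert s.ci_lo == pytest.approx(s["median"]) == pytest.approx(s.ci_hi)

    def test_identical_clones_give_zero_width_fixed_effect_ci(self, ref_params):
        # every subject is the same record, so every resample refits the
        # same dataset and the fixed-effect CI collapses to a point
        cfg = StudyDesignConfig(n_subjects=1,
                                samples_per_subject_probs=(0.0, 0.0, 0.0, 1.0))
        base, _ = generate_study(ref_params, cfg, seed=43)
        proto = base.subjects[0]
        clones = tuple(
            SubjectRecord(f"c{rep}", proto.covariates, proto.doses,
                          proto.observations)
            for rep in range(24)
        )
        ds = handle_blq(PKDataset(subjects=clones))
        b = bootstrap(ds, ref_params, n_replicates=6, seed=3)
        s = b.summary.loc["tvcl"]
        assert (s.ci_hi - s.ci_lo) / s["median"] < 1e-9

    def test_convergence_accounting_and_ci_order(self, ref_params):
        ds, _ = generate_study(ref_params, StudyDesignConfig(n_subjects=24), seed=47)
        ds = handle_blq(ds)
        b = bootstrap(ds, ref_params, n_replicates=15, seed=7)
        assert 0.0 < b.convergence_fraction <= 100.0
        assert (b.summary.ci_lo <= b.summary["median"]).all()
        assert (b.summary["median"] <= b.summary.ci_hi).all()
        assert b.n_replicates == 15

    def test_reproducible_under_seed(self, ref_params):
        ds, _ = generate_study(ref_params, StudyDesignConfig(n_subjects=12), seed=49)
        ds = handle_blq(ds)
        b1 = bootstrap(ds, ref_params, n_replicates=5, seed=21)
        b2 = bootstrap(ds, ref_params, n_replicates=5, seed=21)
        assert b1.summary.equals(b2.summary)

    def test_true_value_inside_ci_on_study_design(self, ref_params):
        ds, _ = generate_study(ref_params, seed=53)
        ds = handle_blq(ds)
        b = bootstrap(ds, ref_params, n_replicates=30, seed=11)
        s = b.summary.loc["tvcl"]
        assert s.ci_lo <= ref_params.tvcl <= s.ci_hi
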
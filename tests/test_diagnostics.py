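import numpy as np
import pytest

from poppk import PopPKModel, predict_concentration
from poppk.data import ConcentrationRecord, DoseEvent, Subject, TrialDataset
from poppk.diagnostics import bootstrap, gof, npde, simulate_observations, vpc
from poppk.estimation import PopPKResults
from poppk.model import (
    PopulationModel,
    ResidualModel,
    individual_typical_params,
)
from poppk.trial import TrialDesign, generate_trial

import pandas as pd

TYPICAL = {"ka": 0.58, "tlag": 0.35, "v": 26.21, "v2": 26.60, "cl": 1.07,
           "cl2": 0.75}


def results_at(spec, ds, etas=None):
    """Results object pinned at a known specification (no fitting)."""
    model = PopPKModel(ds, spec)
    q = len(spec.eta_params)
    etas = etas or {s.id: np.zeros(q) for s in ds.subjects}
    labels = model.packing.labels
    return PopPKResults(
        model=model,
        spec=spec,
        params=pd.Series(np.nan, index=labels),
        rse_percent=None,
        ofv=np.nan,
        n_obs=model.n_obs,
        n_params=model.packing.n,
        etas=etas,
        converged=True,
    )


class TestGof:
    def test_cwres_calibrated_under_true_model(self, final):
        ds = generate_trial(seed=31)
        # empirical-Bayes etas at the known truth, no fitting
        cache = {}
        PopPKModel(ds, final).objective_at(final, eta_cache=cache)
        fit = results_at(final, ds, etas=cache)
        table = gof(fit).table
        assert abs(table["CWRES"].mean()) < 0.2
        frac_within_2 = (table["CWRES"].abs() < 2).mean()
        assert frac_within_2 > 0.85

    def test_exact_data_gives_ipred_equal_dv(self):
        spec = PopulationModel(
            typical=TYPICAL, iiv={}, sigma=ResidualModel(prop_sd=0.1)
        )
        sid = "A"
        subj = Subject(id=sid, dose_mg=300.0, covariates={})
        times = [2.0, 8.0, 24.0]
        f = predict_concentration(
            individual_typical_params(spec, subj), [(0.0, 300.0)], times
        ).concentrations
        ds = TrialDataset(
            [subj],
            [DoseEvent(sid, 0.0, 300.0)],
            [ConcentrationRecord(sid, t, dv) for t, dv in zip(times, f)],
        )
        table = gof(results_at(spec, ds)).table
        np.testing.assert_allclose(table["IPRED"], table["DV"], rtol=1e-12)
        np.testing.assert_allclose(table["CWRES"], 0.0, atol=1e-10)

    def test_scalar_cwres_without_iiv(self):
        spec = PopulationModel(
            typical=TYPICAL, iiv={}, sigma=ResidualModel("additive", add_sd=100.0)
        )
        subj = Subject(id="A", dose_mg=300.0, covariates={})
        f = predict_concentration(
            individual_typical_params(spec, subj), [(0.0, 300.0)], [8.0]
        ).concentrations[0]
        ds = TrialDataset(
            [subj],
            [DoseEvent("A", 0.0, 300.0)],
            [ConcentrationRecord("A", 8.0, f + 250.0)],
        )
        table = gof(results_at(spec, ds)).table
        assert table["CWRES"].iloc[0] == pytest.approx(2.5, rel=1e-9)


class TestBootstrap:
    @pytest.fixture(scope="class")
    def cloned_fit(self, reduced_model):
        # one subject cloned over a single arm: no resampling variance
        design = TrialDesign(arms={300: 4}, dropout=0.0)
        base = generate_trial(design=design, truth=reduced_model, seed=32)
        first = base.subjects[0]
        subjects, doses, obs = [], [], []
        for k in range(4):
            sid = f"C{k}"
            subjects.append(Subject(id=sid, dose_mg=300.0,
                                    covariates=first.covariates))
            for d in base.doses_for(first.id):
                doses.append(DoseEvent(sid, d.time, d.amount))
            for r in base.observations:
                if r.subject_id == first.id:
                    obs.append(ConcentrationRecord(sid, r.time, r.dv, r.is_blq))
        ds = TrialDataset(subjects, doses, obs)
        fit = PopPKModel(ds, reduced_model).fit(compute_rse=False, maxiter=80,
                                                restarts=1)
        return fit

    def test_cloned_subjects_give_degenerate_ci(self, cloned_fit, reduced_model):
        boot = bootstrap(cloned_fit, n=3, seed=1, maxiter=80, restarts=1)
        width = boot.summary["ci_hi"] - boot.summary["ci_lo"]
        assert boot.n_success == 3
        assert (width.loc[["tv_cl", "tv_v"]] < 1e-6).all()

    def test_seeded_bootstrap_is_reproducible(self, cloned_fit):
        b1 = bootstrap(cloned_fit, n=2, seed=9, maxiter=60, restarts=1)
        b2 = bootstrap(cloned_fit, n=2, seed=9, maxiter=60, restarts=1)
        pd.testing.assert_frame_equal(b1.summary, b2.summary)


class TestSimulationHarness:
    def test_shapes_and_determinism(self, final):
        ds = generate_trial(seed=33)
        a = simulate_observations(final, ds, 7, np.random.default_rng(5))
        b = simulate_observations(final, ds, 7, np.random.default_rng(5))
        for sid in a:
            assert a[sid].shape[0] == 7
            np.testing.assert_array_equal(a[sid], b[sid])


class TestVpc:
    @pytest.fixture(scope="class")
    def ds(self, final):
        return generate_trial(seed=34)

    def test_self_consistent_model_covers_observed_median(self, final, ds):
        res = vpc(final, ds, n=200, seed=1)
        t = res.table
        inside = (
            (t["obs_p50"] >= t["sim_p50_lo"]) & (t["obs_p50"] <= t["sim_p50_hi"])
        )
        assert inside.mean() > 0.7
        assert (t["sim_p5_lo"] <= t["sim_p5_hi"]).all()

    def test_single_replicate_gives_degenerate_ci(self, final, ds):
        res = vpc(final, ds, n=1, seed=2)
        t = res.table
        np.testing.assert_allclose(t["sim_p50_lo"], t["sim_p50_hi"])

    def test_misspecified_clearance_detected(self, final, ds):
        wrong = final.copy()
        wrong.typical = {**wrong.typical, "cl": wrong.typical["cl"] / 2.0}
        res = vpc(wrong, ds, n=200, seed=3)
        t = res.table
        outside = (
            (t["obs_p50"] < t["sim_p50_lo"]) | (t["obs_p50"] > t["sim_p50_hi"])
        )
        assert outside.mean() > 0.5

    def test_time_window_restricts_bins(self, final, ds):
        res = vpc(final, ds, n=50, seed=4, time_window=(576.0, 600.0))
        assert (res.table["bin"] >= 576.0).all()
        res_tad = vpc(final, ds, n=50, seed=4, by="tad")
        assert res_tad.table["bin"].max() <= 96.0


class TestNpde:
    def test_null_distribution_is_standard_normal(self, final):
        ds = generate_trial(seed=35)
        res = npde(final, ds, n=1000, seed=6)
        assert abs(res.mean) < 0.15
        assert 0.8 < res.variance < 1.25
        assert np.isfinite(res.shapiro_p)

    def test_underdetermined_simulation_rejected(self, final):
        ds = generate_trial(seed=36)
        with pytest.raises(ValueError):
            npde(final, ds, n=1, seed=0)

    def test_decorrelation_matches_hand_computation(self):
        # additive-error model, no IIV: the ensemble covariance approaches
        # sigma^2 I, so the decorrelated residual is (y - mean)/sd and the
        # NPDE is the normal quantile of the empirical rank
        spec = PopulationModel(
            typical=TYPICAL, iiv={},
            sigma=ResidualModel("additive", add_sd=200.0),
        )
        subj = Subject(id="A", dose_mg=300.0, covariates={})
        times = [4.0, 24.0]
        f = predict_concentration(
            individual_typical_params(spec, subj), [(0.0, 300.0)], times
        ).concentrations
        ds = TrialDataset(
            [subj],
            [DoseEvent("A", 0.0, 300.0)],
            [ConcentrationRecord("A", t, dv) for t, dv in zip(times, f)],
        )
        n = 4000
        res = npde(spec, ds, n=n, seed=7)
        # DV == model expectation, so each rank probability is ~0.5
        from scipy.stats import norm

        for val in res.table["NPDE"]:
            assert abs(norm.cdf(val) - 0.5) < 0.03
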
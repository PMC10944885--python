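import numpy as np
import pytest

from poppk import PopPKModel, compare, objective, predict_concentration
from poppk.data import ConcentrationRecord, DoseEvent, Subject, TrialDataset
from poppk.model import (
    CovariateEffect,
    PopulationModel,
    ResidualModel,
    individual_params,
)
from poppk.structural import PKParameters

TYPICAL = {"ka": 0.58, "tlag": 0.35, "v": 26.21, "v2": 26.60, "cl": 1.07,
           "cl2": 0.75}


def build_dataset(n_subjects, times, dose=300.0, eta_cl=None, noise_sd=0.15,
                  seed=0, truth=None):
    """Small dataset simulated from the structural model."""
    rng = np.random.default_rng(seed)
    truth = truth or PopulationModel(
        typical=TYPICAL, iiv={}, sigma=ResidualModel(prop_sd=noise_sd)
    )
    subjects, doses, obs = [], [], []
    for i in range(n_subjects):
        sid = f"S{i}"
        subjects.append(Subject(id=sid, dose_mg=dose, covariates={}))
        doses.append(DoseEvent(subject_id=sid, time=0.0, amount=dose))
        eta = {"cl": eta_cl[i]} if eta_cl is not None else {}
        p = individual_params(truth, subjects[-1], eta)
        f = predict_concentration(p, [(0.0, dose)], times).concentrations
        y = f * (1.0 + noise_sd * rng.standard_normal(len(times)))
        for t, dv in zip(times, np.maximum(y, 60.0)):
            obs.append(ConcentrationRecord(subject_id=sid, time=t, dv=dv))
    return TrialDataset(subjects, doses, obs)


class TestObjective:
    def test_no_iiv_additive_equals_weighted_least_squares(self):
        times = [2.0, 8.0, 24.0, 48.0]
        ds = build_dataset(3, times, seed=1)
        sigma_add = 500.0
        m = PopulationModel(
            typical=TYPICAL, iiv={}, sigma=ResidualModel("additive",
                                                         add_sd=sigma_add)
        )
        ofv = objective(m, ds)
        p = PKParameters(**TYPICAL)
        expected = 0.0
        for s in ds.subjects:
            recs = ds.observations_for(s.id)
            t = [r.time for r in recs]
            y = np.array([r.dv for r in recs])
            f = predict_concentration(p, [(0.0, s.dose_mg)], t).concentrations
            expected += np.sum(
                (y - f) ** 2 / sigma_add**2 + np.log(2 * np.pi * sigma_add**2)
            )
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_matches_quadrature_oracle_single_eta(self):
        """FOCE OFV vs adaptive numerical integration over one eta."""
        from scipy.integrate import quad

        times = [2.0, 8.0, 24.0]
        omega2 = 0.08
        rng = np.random.default_rng(3)
        eta_true = rng.normal(0, np.sqrt(omega2), 2)
        ds = build_dataset(2, times, eta_cl=eta_true, noise_sd=0.1, seed=4)
        m = PopulationModel(
            typical=TYPICAL, iiv={"cl": omega2},
            sigma=ResidualModel(prop_sd=0.1),
        )
        ofv = objective(m, ds)

        p0 = PKParameters(**TYPICAL)
        exact = 0.0
        for s in ds.subjects:
            recs = ds.observations_for(s.id)
            t = [r.time for r in recs]
            y = np.array([r.dv for r in recs])

            def integrand(eta):
                p = PKParameters(**{**TYPICAL, "cl": TYPICAL["cl"] * np.exp(eta)})
                f = predict_concentration(p, [(0.0, s.dose_mg)], t).concentrations
                v = (0.1 * np.maximum(f, 0.5)) ** 2
                like = np.prod(
                    np.exp(-0.5 * (y - f) ** 2 / v) / np.sqrt(2 * np.pi * v)
                )
                prior = np.exp(-0.5 * eta**2 / omega2) / np.sqrt(2 * np.pi * omega2)
                return like * prior

            marginal, _ = quad(integrand, -2.5, 2.5, limit=200)
            exact += -2.0 * np.log(marginal)
        # the FOCE approximation should agree closely on a near-Gaussian toy
        assert ofv == pytest.approx(exact, rel=0.005)

    def test_duplicating_subjects_doubles_ofv(self):
        times = [2.0, 8.0, 24.0, 48.0]
        ds = build_dataset(2, times, seed=5)
        m = PopulationModel(
            typical=TYPICAL, iiv={"cl": 0.05}, sigma=ResidualModel(prop_sd=0.15)
        )
        doubled = TrialDataset(
            subjects=ds.subjects
            + [Subject(id=s.id + "x", dose_mg=s.dose_mg, covariates=s.covariates)
               for s in ds.subjects],
            doses=ds.doses
            + [DoseEvent(d.subject_id + "x", d.time, d.amount) for d in ds.doses],
            observations=ds.observations
            + [ConcentrationRecord(r.subject_id + "x", r.time, r.dv, r.is_blq)
               for r in ds.observations],
        )
        assert objective(m, doubled) == pytest.approx(2 * objective(m, ds),
                                                      rel=1e-8)

    def test_invariant_to_subject_order(self):
        times = [2.0, 8.0, 24.0]
        ds = build_dataset(3, times, seed=6)
        m = PopulationModel(
            typical=TYPICAL, iiv={"cl": 0.05}, sigma=ResidualModel(prop_sd=0.15)
        )
        reversed_ds = TrialDataset(
            subjects=ds.subjects[::-1], doses=ds.doses, observations=ds.observations
        )
        assert objective(m, ds) == pytest.approx(objective(m, reversed_ds),
                                                 rel=1e-10)

    def test_non_psd_omega_penalised(self):
        times = [2.0, 8.0, 24.0]
        ds = build_dataset(2, times, seed=7)
        m = PopulationModel(
            typical=TYPICAL, iiv={"cl": 0.05, "v": 0.05},
            omega_corr=np.array([[1.0, 1.0], [1.0, 1.0]]),  # singular
            sigma=ResidualModel(prop_sd=0.15),
        )
        assert objective(m, ds) == 1e12


class TestFit:
    def test_noise_free_dense_data_recovers_truth(self):
        times = list(np.arange(1.0, 97.0, 3.0))
        ds = build_dataset(4, times, noise_sd=1e-12, seed=8)
        m = PopulationModel(
            typical=TYPICAL, iiv={}, sigma=ResidualModel(prop_sd=0.1)
        )
        res = PopPKModel(ds, m).fit(compute_rse=False, maxiter=300, restarts=1)
        # residual noise shrinks toward zero and the structural parameters
        # stay at their generating values (the surface grows ill-conditioned
        # as sigma -> 0, so the structural tolerance is a loose 5%)
        assert res.params["sigma_prop"] < 0.02
        assert res.params["tv_cl"] == pytest.approx(1.07, rel=0.05)
        assert res.params["tv_v"] == pytest.approx(26.21, rel=0.05)

    def test_information_criteria_relations(self, reduced_model, trial_seed1):
        model = PopPKModel(trial_seed1, reduced_model)
        res = model.fit(compute_rse=False, maxiter=60, restarts=1)
        assert res.aic == pytest.approx(res.ofv + 2 * res.n_params)
        assert res.bic == pytest.approx(
            res.ofv + res.n_params * np.log(res.n_obs)
        )
        assert np.isfinite(res.ofv)
        summary = res.summary()
        assert "OFV" in summary and "tv_cl" in summary

    def test_overparameterised_model_warns(self):
        times = [2.0, 8.0]
        ds = build_dataset(1, times, seed=9)
        m = PopulationModel(
            typical=TYPICAL,
            iiv={"cl": 0.05, "v": 0.05, "ka": 0.1, "tlag": 0.1},
            sigma=ResidualModel(prop_sd=0.15),
        )
        with pytest.warns(UserWarning, match="identifiable"):
            PopPKModel(ds, m)


class TestNonDiagonalOmega:
    def test_cholesky_packing_round_trips(self):
        corr = np.array([[1.0, 0.4], [0.4, 1.0]])
        m = PopulationModel(
            typical=TYPICAL, iiv={"v": 0.05, "cl": 0.08}, omega_corr=corr,
            sigma=ResidualModel(prop_sd=0.15),
        )
        from poppk.estimation import _Packing

        packing = _Packing(m)
        back = packing.unpack(packing.pack(m))
        np.testing.assert_allclose(back.omega_matrix(), m.omega_matrix(),
                                   rtol=1e-12)
        assert any(lab.startswith("omega_chol_") for lab in packing.labels)

    def test_fit_with_correlated_iiv_runs(self):
        times = [2.0, 8.0, 24.0, 48.0]
        rng = np.random.default_rng(11)
        eta = rng.normal(0, 0.3, 6)
        ds = build_dataset(6, times, eta_cl=eta, seed=12)
        m = PopulationModel(
            typical=TYPICAL, iiv={"v": 0.05, "cl": 0.08},
            omega_corr=np.array([[1.0, 0.3], [0.3, 1.0]]),
            sigma=ResidualModel(prop_sd=0.15),
        )
        res = PopPKModel(ds, m, fix_typical=("ka", "tlag", "v2", "cl2")).fit(
            compute_rse=False, maxiter=40, restarts=1
        )
        omega = res.spec.omega_matrix()
        assert np.all(np.linalg.eigvalsh(omega) > 0)
        assert np.isfinite(res.ofv)


class TestStandardErrors:
    def test_rse_positive_and_finite(self, reduced_model, trial_seed1):
        res = PopPKModel(trial_seed1, reduced_model,
                         fix_typical=("ka", "tlag", "v2", "cl2")).fit(
            maxiter=100, restarts=1
        )
        assert res.rse_percent is not None
        finite = res.rse_percent.dropna()
        assert len(finite) >= 3
        assert (finite > 0).all()
        assert (finite < 200).all()


class TestCompare:
    def test_published_forward_step_delta_accepted(self):
        class Stub:
            def __init__(self, ofv):
                self.ofv = ofv

        decision = compare(Stub(7857.55), Stub(7845.80), threshold=3.84)
        assert decision.delta_ofv == pytest.approx(11.75)
        assert decision.accept

    def test_zero_delta_rejected(self):
        class Stub:
            def __init__(self, ofv):
                self.ofv = ofv

        assert not compare(Stub(100.0), Stub(100.0), threshold=3.84).accept
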
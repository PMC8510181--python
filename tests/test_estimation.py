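"""Estimation-engine tests: OFV correctness against closed forms and the
quadrature oracle, empirical Bayes estimates, shrinkage behaviour, and the
stepwise covariate search."""

import math

import numpy as np
import pytest

from oracles import grid_search_ebe, quadrature_ofv

from vancopk.pk_core import PopulationParams, concentration, individual_params
from vancopk.estimation import (
    CovariateEffect,
    ModelSpec,
    base_model_spec,
    final_model_spec,
    fit,
    ofv,
    posthoc_ebe,
    shrinkage,
    stepwise_covariate_search,
    FORWARD_THRESHOLD,
    BACKWARD_THRESHOLD,
)
from vancopk.synthetic import SamplingDesignSpec, simulate_dataset

ONE_EPISODE = SamplingDesignSpec(episodes_per_subject_mean=1.0)


def _dense_design(extra=8.0):
    return SamplingDesignSpec(extra_samples_mean=extra, episodes_per_subject_mean=1.0)


class TestOFV:
    def test_no_random_effects_reduces_to_gaussian_m2ll(self):
        p = PopulationParams(omega_cl=0.0, omega_v=0.0, sigma_prop=0.2, sigma_add=0.5)
        data = simulate_dataset(8, p=p, design=ONE_EPISODE, seed=21)
        expected = 0.0
        for record in data:
            ip = individual_params(record.covariates, p)
            for obs in record.observations:
                f = concentration(obs.time, record.doses, ip)
                var = p.sigma_add**2 + (p.sigma_prop * f) ** 2
                expected += (obs.concentration - f) ** 2 / var + math.log(2 * math.pi * var)
        assert ofv(data, final_model_spec(), p) == pytest.approx(expected, rel=1e-10)

    def test_duplicated_subject_doubles_ofv(self):
        p = PopulationParams(sigma_add=0.3)
        data = simulate_dataset(6, p=p, design=ONE_EPISODE, seed=22)
        single = ofv(data, final_model_spec(), p)
        doubled = ofv(data + data, final_model_spec(), p)
        assert doubled == pytest.approx(2 * single, rel=1e-9)

    def test_two_subject_toy_matches_quadrature(self):
        # one active random effect, one observation per subject
        p = PopulationParams(
            omega_cl=0.35, omega_v=0.0, sigma_prop=0.15, sigma_add=0.5
        )
        data = simulate_dataset(
            2, p=p, design=SamplingDesignSpec(extra_samples_mean=0.0, episodes_per_subject_mean=1.0), seed=23
        )
        laplace = ofv(data, final_model_spec(), p)
        oracle = quadrature_ofv(data, p, n_nodes=64)
        assert laplace == pytest.approx(oracle, abs=0.1)

    def test_ofv_invariant_to_subject_order(self):
        p = PopulationParams(sigma_add=0.3)
        data = simulate_dataset(12, p=p, design=ONE_EPISODE, seed=24)
        forward = ofv(data, final_model_spec(), p)
        backward = ofv(list(reversed(data)), final_model_spec(), p)
        assert forward == backward  # fsum over subjects: exactly order-free


class TestFit:
    def test_noise_free_identification(self):
        truth = PopulationParams(
            omega_cl=0.0, omega_v=0.0, sigma_prop=0.02, sigma_add=1e-4
        )
        data = simulate_dataset(25, p=truth, design=_dense_design(4.0), seed=31)
        res = fit(
            data,
            final_model_spec("proportional"),
            compute_se=False,
            compute_ebes=False,
            polish_rounds=1,
        )
        assert res.converged
        assert res.params["theta_cl"] == pytest.approx(0.29, rel=0.01)
        assert res.params["theta_v"] == pytest.approx(1.00, rel=0.01)
        assert res.params["beta_scr_CL"] == pytest.approx(-0.70, abs=0.02)

    def test_estimates_invariant_to_subject_order(self):
        p = PopulationParams(omega_cl=0.3, omega_v=0.3, sigma_prop=0.15, sigma_add=1e-4)
        data = simulate_dataset(15, p=p, design=ONE_EPISODE, seed=32)
        a = fit(data, base_model_spec("proportional"), compute_se=False, compute_ebes=False,
                polish_rounds=0)
        b = fit(list(reversed(data)), base_model_spec("proportional"), compute_se=False,
                compute_ebes=False, polish_rounds=0)
        for key in a.params:
            assert a.params[key] == pytest.approx(b.params[key], rel=1e-6)

    def test_fit_reports_problem_size(self):
        p = PopulationParams(sigma_add=0.3)
        data = simulate_dataset(10, p=p, design=ONE_EPISODE, seed=33)
        res = fit(data, base_model_spec(), compute_se=False, compute_ebes=False,
                  maxiter=30, polish_rounds=0)
        assert res.n_subjects == len(data)
        assert res.n_observations == sum(len(r.observations) for r in data)


class TestPosthoc:
    def test_no_observations_returns_prior_mode(self, median_covariates, final_params):
        from vancopk.pk_core import SubjectRecord, DoseEvent

        empty = SubjectRecord("s1", median_covariates, [DoseEvent(0.0, 136.5)], [])
        assert posthoc_ebe(empty, final_model_spec(), final_params) == (0.0, 0.0)

    def test_matches_grid_search_oracle(self):
        p = PopulationParams(omega_cl=0.4, omega_v=0.4, sigma_prop=0.1, sigma_add=0.2)
        record = simulate_dataset(1, p=p, design=_dense_design(6.0), seed=41)[0]
        eta = posthoc_ebe(record, final_model_spec(), p)
        coarse = grid_search_ebe(record, p, half_width=1.5, n_grid=121)
        assert eta[0] == pytest.approx(coarse[0], abs=0.03)
        assert eta[1] == pytest.approx(coarse[1], abs=0.03)

    def test_rich_noise_free_data_recovers_eta(self):
        truth_eta = (0.35, -0.25)
        p = PopulationParams(omega_cl=0.4, omega_v=0.4, sigma_prop=1e-3, sigma_add=1e-6)
        record = simulate_dataset(
            1,
            p=PopulationParams(omega_cl=0.0, omega_v=0.0, sigma_prop=1e-12, sigma_add=1e-12),
            design=_dense_design(10.0),
            seed=42,
        )[0]
        # rebuild observations at the chosen eta, exactly noise-free
        ip = individual_params(record.covariates, p, *truth_eta)
        times = np.array([o.time for o in record.observations])
        from vancopk.pk_core import Observation

        record.observations = [
            Observation(float(t), float(c))
            for t, c in zip(times, concentration(times, record.doses, ip))
        ]
        eta = posthoc_ebe(record, final_model_spec(), p)
        assert eta[0] == pytest.approx(truth_eta[0], abs=1e-3)
        assert eta[1] == pytest.approx(truth_eta[1], abs=1e-3)

    def test_vanishing_omega_shrinks_ebes_to_zero(self):
        p_wide = PopulationParams(omega_cl=0.4, omega_v=0.4, sigma_prop=0.3, sigma_add=0.3)
        record = simulate_dataset(1, p=p_wide, design=ONE_EPISODE, seed=43)[0]
        p_tiny = PopulationParams(omega_cl=1e-3, omega_v=1e-3, sigma_prop=0.3, sigma_add=0.3)
        eta = posthoc_ebe(record, final_model_spec(), p_tiny)
        assert abs(eta[0]) < 1e-3 and abs(eta[1]) < 1e-3


class TestShrinkage:
    def _fit(self, design, seed, n=40):
        p = PopulationParams(omega_cl=0.4, omega_v=0.4, sigma_prop=0.1, sigma_add=1e-4)
        data = simulate_dataset(n, p=p, design=design, seed=seed)
        return fit(data, base_model_spec("proportional"), compute_se=False, polish_rounds=1)

    def test_dense_design_has_low_eta_shrinkage_and_sparse_is_higher(self):
        dense = self._fit(_dense_design(10.0), seed=51)
        sparse = self._fit(
            SamplingDesignSpec(extra_samples_mean=0.0, episodes_per_subject_mean=1.0), seed=51
        )
        shr_dense = shrinkage(dense)
        shr_sparse = shrinkage(sparse)
        assert shr_dense[0] < 0.25
        assert shr_sparse[0] > shr_dense[0]
        assert shr_sparse[1] > shr_dense[1]

    def test_noise_free_iwres_gives_full_eps_shrinkage(self):
        # residuals identically ~0 => SD(IWRES) ~ 0 => eps-shrinkage ~ 1
        truth = PopulationParams(omega_cl=0.3, omega_v=0.3, sigma_prop=1e-6, sigma_add=1e-9)
        data = simulate_dataset(10, p=truth, design=_dense_design(4.0), seed=52)
        res = fit(data, base_model_spec("proportional"), compute_se=False, polish_rounds=1)
        assert shrinkage(res)[2] > 0.9


class TestStepwise:
    def test_strong_scr_effect_selected_and_protected(self):
        truth = PopulationParams(
            omega_cl=0.25, omega_v=0.25, sigma_prop=0.15, sigma_add=1e-4
        )  # exp_scr = -0.70 is in effect via defaults
        data = simulate_dataset(35, p=truth, design=ONE_EPISODE, seed=61)
        candidates = [CovariateEffect("scr", "CL"), CovariateEffect("albumin", "CL")]
        result = stepwise_covariate_search(
            data, base_model_spec("proportional"), candidates
        )
        kept = {e.key for e in result.selected_spec.covariate_effects}
        assert "beta_scr_CL" in kept
        # deletion-step record: removing sCr must cost far more than 7.88
        back = result.table[
            (result.table.phase == "backward") & (result.table.covariate == "scr")
        ]
        assert (back.delta_ofv > BACKWARD_THRESHOLD).all()
        assert result.final_fit.params["beta_scr_CL"] == pytest.approx(-0.70, abs=0.25)

    def test_thresholds_are_chi2_quantiles(self):
        from scipy.stats import chi2

        assert FORWARD_THRESHOLD == pytest.approx(chi2.ppf(0.95, 1), abs=0.005)
        assert BACKWARD_THRESHOLD == pytest.approx(chi2.ppf(0.995, 1), abs=0.01)

    def test_screening_table_shape(self):
        truth = PopulationParams(omega_cl=0.3, omega_v=0.3, sigma_prop=0.2, sigma_add=1e-4)
        data = simulate_dataset(15, p=truth, design=ONE_EPISODE, seed=62)
        result = stepwise_covariate_search(
            data,
            base_model_spec("proportional"),
            [CovariateEffect("albumin", "CL")],
        )
        uni = result.table[result.table.phase == "univariate"]
        assert set(uni.columns) >= {"phase", "covariate", "parameter", "delta_ofv", "converged"}
        assert len(uni) == 1
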
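"""Structural-model unit and property tests.

Closed-form one-compartment infusion kinetics are checked against hand
arithmetic, an independent ODE integration, superposition/linearity
properties, and the steady-state identities used by the dosing simulations.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ode_concentration, trapezoid_auc

from vancopk.pk_core import (
    CovariateSet,
    DoseEvent,
    IndividualParams,
    InvalidInputError,
    InvalidRegimenError,
    Observation,
    PopulationParams,
    RegimenSpec,
    auc24_at_steady_state,
    concentration,
    individual_params,
    steady_state_trough,
    typical_clearance,
    typical_volume,
)


class TestCovariateModel:
    def test_reference_subject_clearance_is_theta(self, median_covariates, final_params):
        # at 1 kg and reference sCr/DFLT every multiplier is 1
        cov = CovariateSet(
            weight=1.0, height=48.0, age=1.0, sex="male", scr=0.16, dflt=17.0,
            albumin=3.1, alt=54.7, underlying_disease="other",
        )
        assert typical_clearance(cov, final_params) == pytest.approx(0.29)

    def test_median_subject_clearance(self, median_covariates, final_params):
        expected = 0.29 * 9.1**0.75  # = 1.5194...
        assert typical_clearance(median_covariates, final_params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.52, abs=0.005)

    def test_doubling_scr_scales_by_power(self, median_covariates, final_params):
        base = typical_clearance(median_covariates, final_params)
        doubled = CovariateSet(**{**median_covariates.__dict__, "scr": 0.32})
        assert typical_clearance(doubled, final_params) == pytest.approx(base * 2 ** (-0.70), rel=1e-12)

    @pytest.mark.parametrize("weight,expected", [(1.0, 1.0), (9.1, 9.1), (61.0, 61.0)])
    def test_volume_linear_in_weight(self, weight, expected, median_covariates, final_params):
        cov = CovariateSet(**{**median_covariates.__dict__, "weight": weight})
        assert typical_volume(cov, final_params) == pytest.approx(expected)

    def test_clearance_monotone_decreasing_in_scr_and_dflt(self, median_covariates, final_params):
        grid = np.linspace(0.08, 2.0, 25)
        cls = [
            typical_clearance(
                CovariateSet(**{**median_covariates.__dict__, "scr": s}), final_params
            )
            for s in grid
        ]
        assert all(a > b for a, b in zip(cls, cls[1:]))
        dflt_grid = np.linspace(1.0, 200.0, 25)
        cls = [
            typical_clearance(
                CovariateSet(**{**median_covariates.__dict__, "dflt": d}), final_params
            )
            for d in dflt_grid
        ]
        assert all(a > b for a, b in zip(cls, cls[1:]))

    def test_dflt_zero_uses_floor(self, median_covariates, final_params):
        at_zero = CovariateSet(**{**median_covariates.__dict__, "dflt": 0.0})
        at_floor = CovariateSet(**{**median_covariates.__dict__, "dflt": 1.0})
        assert typical_clearance(at_zero, final_params) == pytest.approx(
            typical_clearance(at_floor, final_params)
        )
        assert math.isfinite(typical_clearance(at_zero, final_params))

    def test_invalid_covariates_rejected(self):
        with pytest.raises(InvalidInputError):
            CovariateSet(weight=-1, height=70, age=12, sex="male", scr=0.2, dflt=5,
                         albumin=3, alt=50, underlying_disease="other")
        with pytest.raises(InvalidInputError):
            CovariateSet(weight=10, height=70, age=12, sex="male", scr=0.0, dflt=5,
                         albumin=3, alt=50, underlying_disease="other")


class TestIndividualParams:
    def test_eta_zero_gives_typical_values(self, median_covariates, final_params):
        ip = individual_params(median_covariates, final_params, 0.0, 0.0)
        assert ip.cl == pytest.approx(typical_clearance(median_covariates, final_params))
        assert ip.v == pytest.approx(typical_volume(median_covariates, final_params))

    def test_eta_algebra(self, median_covariates, final_params):
        base = individual_params(median_covariates, final_params)
        doubled = individual_params(median_covariates, final_params, math.log(2), 0.0)
        assert doubled.cl == pytest.approx(2 * base.cl, rel=1e-12)
        assert doubled.v == pytest.approx(base.v, rel=1e-12)
        quartered = individual_params(median_covariates, final_params, -math.log(2), math.log(2))
        assert quartered.k_e == pytest.approx(base.k_e / 4, rel=1e-12)

    def test_nonfinite_eta_rejected(self, median_covariates, final_params):
        with pytest.raises(InvalidInputError):
            individual_params(median_covariates, final_params, float("nan"), 0.0)


class TestConcentration:
    def test_zero_before_and_at_first_dose(self):
        ip = IndividualParams(cl=1.52, v=9.19)
        doses = [DoseEvent(0.0, 136.5, 1.0)]
        assert concentration(0.0, doses, ip) == 0.0

    def test_end_of_infusion_value(self):
        # (R/CL)(1 - e^{-ke * 1}) with R = 136.5 mg/h
        ip = IndividualParams(cl=1.52, v=9.19)
        expected = (136.5 / 1.52) * (1 - math.exp(-(1.52 / 9.19) * 1.0))
        got = concentration(1.0, [DoseEvent(0.0, 136.5, 1.0)], ip)
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(13.7, abs=0.1)

    def test_steady_state_limit_of_constant_infusion(self):
        ip = IndividualParams(cl=2.0, v=10.0)
        rate = 50.0  # mg/h forever, approximated by one very long infusion
        dose = DoseEvent(0.0, rate * 10000.0, 10000.0)
        assert concentration(5000.0, [dose], ip) == pytest.approx(rate / ip.cl, rel=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(
        cl=st.floats(0.3, 5.0),
        v=st.floats(2.0, 40.0),
        t=st.floats(0.0, 40.0),
        gap=st.floats(2.0, 12.0),
        amt1=st.floats(20.0, 400.0),
        amt2=st.floats(20.0, 400.0),
    )
    def test_superposition(self, cl, v, t, gap, amt1, amt2):
        ip = IndividualParams(cl=cl, v=v)
        d1, d2 = DoseEvent(0.0, amt1, 1.0), DoseEvent(gap, amt2, 1.0)
        together = concentration(t, [d1, d2], ip)
        separate = concentration(t, [d1], ip) + concentration(t, [d2], ip)
        assert together == pytest.approx(separate, rel=1e-9, abs=1e-12)

    def test_closed_form_matches_ode_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            cl = float(rng.uniform(0.3, 5.0))
            v = float(rng.uniform(2.0, 40.0))
            doses = sorted(
                (
                    DoseEvent(
                        float(k * rng.uniform(4, 8)),
                        float(rng.uniform(50, 500)),
                        float(rng.uniform(0.5, 2.0)),
                    )
                    for k in range(3)
                ),
                key=lambda d: d.start_time,
            )
            t = rng.uniform(0.1, 30.0, size=4)
            ours = concentration(t, doses, IndividualParams(cl, v))
            oracle = ode_concentration(t, doses, cl, v)
            np.testing.assert_allclose(ours, oracle, rtol=1e-6, atol=1e-9)


class TestSteadyState:
    def test_trough_matches_superposition_at_dose_30(self, median_covariates):
        reg = RegimenSpec(15.0, 6.0, 1.0)
        ip = IndividualParams(cl=1.52, v=9.19)
        closed = steady_state_trough(reg, median_covariates, ip)
        doses = [
            DoseEvent(k * reg.interval, reg.dose_mg_per_kg * median_covariates.weight, 1.0)
            for k in range(30)
        ]
        brute = concentration(29 * reg.interval - 1e-9, doses, ip)
        assert closed == pytest.approx(brute, rel=1e-3)

    def test_trough_linear_in_dose(self, median_covariates):
        ip = IndividualParams(cl=1.52, v=9.19)
        t1 = steady_state_trough(RegimenSpec(15.0, 6.0), median_covariates, ip)
        t2 = steady_state_trough(RegimenSpec(30.0, 6.0), median_covariates, ip)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_trough_vanishes_for_fast_elimination(self, median_covariates):
        ip = IndividualParams(cl=500.0, v=5.0)  # k_e = 100/h
        assert steady_state_trough(RegimenSpec(15.0, 6.0), median_covariates, ip) < 1e-10

    def test_interval_must_exceed_infusion(self):
        with pytest.raises(InvalidRegimenError):
            RegimenSpec(15.0, 0.5, infusion_duration=1.0)


class TestAUC24:
    def test_identity_against_trapezoid_oracle(self, median_covariates):
        ip = IndividualParams(cl=1.52, v=9.19)
        closed = auc24_at_steady_state(546.0, ip.cl)
        assert closed == pytest.approx(546.0 / 1.52, rel=1e-12)
        # steady-state day: doses every 6 h, integrate day 10
        doses = [DoseEvent(k * 6.0, 136.5, 1.0) for k in range(50)]
        t = np.linspace(240.0, 264.0, 6001)
        numeric = trapezoid_auc(t, concentration(t, doses, ip))
        assert closed == pytest.approx(numeric, rel=0.01)

    def test_linearity_and_boundary(self):
        assert auc24_at_steady_state(800.0, 2.0) == pytest.approx(
            2 * auc24_at_steady_state(400.0, 2.0)
        )
        # CL = daily_dose / 400 puts AUC24 exactly on the MIC-1 target boundary
        assert auc24_at_steady_state(546.0, 546.0 / 400.0) == pytest.approx(400.0)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            auc24_at_steady_state(0.0, 1.0)
        with pytest.raises(InvalidInputError):
            auc24_at_steady_state(100.0, -1.0)


class TestDomainTypes:
    def test_dose_event_rate(self):
        d = DoseEvent(0.0, 150.0, 2.0)
        assert d.rate * d.duration == pytest.approx(d.amount, rel=1e-12)

    def test_dose_event_validation(self):
        with pytest.raises(InvalidInputError):
            DoseEvent(0.0, -5.0, 1.0)
        with pytest.raises(InvalidInputError):
            DoseEvent(0.0, 100.0, 0.0)

    def test_observation_validation(self):
        with pytest.raises(InvalidInputError):
            Observation(-1.0, 5.0)
        with pytest.raises(InvalidInputError):
            Observation(1.0, -5.0)

    def test_population_params_validation(self):
        with pytest.raises(InvalidInputError):
            PopulationParams(theta_cl=-0.1)
        with pytest.raises(InvalidInputError):
            PopulationParams(sigma_prop=0.0, sigma_add=0.0)

    def test_individual_params_ke(self):
        ip = IndividualParams(cl=3.0, v=12.0)
        assert ip.k_e == pytest.approx(0.25, rel=1e-12)
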
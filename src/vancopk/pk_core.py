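"""Structural pharmacokinetic model for intermittent-infusion vancomycin.

One-compartment disposition with zero-order (constant-rate) intravenous
infusion input and first-order elimination. Clearance carries an allometric
weight term (``wt^0.75``) and power-model covariate effects for serum
creatinine and days-from-liver-transplantation; volume scales linearly with
weight. Between-subject variability enters as log-normal (exponential)
multipliers on clearance and volume.

Units are fixed throughout the package: time in hours, amounts in mg,
volumes in liters, clearances in L/h, and concentrations in ug/mL, which is
numerically identical to mg/L (no conversion layer is needed or provided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseEvent",
    "Observation",
    "CovariateSet",
    "SubjectRecord",
    "PopulationParams",
    "IndividualParams",
    "RegimenSpec",
    "typical_clearance",
    "typical_volume",
    "individual_params",
    "concentration",
    "steady_state_trough",
    "auc24_at_steady_state",
    "profile_matrices",
    "concentration_from_matrices",
]


class InvalidInputError(ValueError):
    """Raised when a physically impossible input is supplied."""


class InvalidRegimenError(ValueError):
    """Raised for dosing regimens that cannot be administered."""


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order intravenous infusion.

    Parameters
    ----------
    start_time:
        Hours since the first dose of the treatment episode.
    amount:
        Dose in mg.
    duration:
        Infusion length in hours (default 1 h, standard practice for
        intermittent vancomycin infusion).
    """

    start_time: float
    amount: float
    duration: float = 1.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise InvalidInputError(f"dose amount must be > 0, got {self.amount}")
        if not self.duration > 0:
            raise InvalidInputError(f"infusion duration must be > 0, got {self.duration}")
        if self.start_time < 0:
            raise InvalidInputError(f"dose start time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h (amount / duration)."""
        return self.amount / self.duration


@dataclass(frozen=True)
class Observation:
    """A measured serum concentration (ug/mL) at a time since first dose."""

    time: float
    concentration: float
    below_quantification: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidInputError(f"observation time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise InvalidInputError(
                f"observed concentration must be >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class CovariateSet:
    """Baseline covariates for one treatment episode.

    ``weight`` kg, ``height`` cm, ``age`` months, ``scr`` (serum creatinine)
    mg/dL, ``dflt`` days from liver transplantation to vancomycin start,
    ``albumin`` g/dL, ``alt`` U/L. ``sex`` is ``"male"``/``"female"`` and
    ``underlying_disease`` is ``"biliary_atresia"``/``"other"``.
    """

    weight: float
    height: float
    age: float
    sex: str
    scr: float
    dflt: float
    albumin: float
    alt: float
    underlying_disease: str

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 200:
            raise InvalidInputError(f"weight must be in (0, 200] kg, got {self.weight}")
        if not 0 < self.scr <= 10:
            raise InvalidInputError(f"sCr must be in (0, 10] mg/dl, got {self.scr}")
        if self.dflt < 0:
            raise InvalidInputError(f"DFLT must be >= 0 days, got {self.dflt}")
        for name in ("height", "age", "albumin", "alt"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidInputError(f"{name} must be > 0, got {value}")
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.underlying_disease not in ("biliary_atresia", "other"):
            raise InvalidInputError(
                "underlying_disease must be 'biliary_atresia' or 'other', "
                f"got {self.underlying_disease!r}"
            )


@dataclass
class SubjectRecord:
    """One treatment episode: covariates plus dosing and sampling history."""

    subject_id: str
    covariates: CovariateSet
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        dose_times = [d.start_time for d in self.doses]
        if dose_times != sorted(dose_times):
            raise InvalidInputError(f"{self.subject_id}: dose times must be non-decreasing")
        obs_times = [o.time for o in self.observations]
        if obs_times != sorted(obs_times):
            raise InvalidInputError(f"{self.subject_id}: observation times must be non-decreasing")


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects, between-subject variability and residual error.

    Defaults are the final-model estimates of the study population this
    package emulates (pediatric liver-transplant recipients):

    ``CL (L/h) = theta_cl * wt^0.75 * (sCr/0.16)^exp_scr * (DFLT/17)^exp_dflt * exp(eta_CL)``
    ``V  (L)   = theta_v  * wt * exp(eta_V)``

    ``omega_*`` are SDs of the normal random effects ``eta``; ``sigma_prop``
    and ``sigma_add`` parameterise the combined residual model
    ``y = f * (1 + eps_prop) + eps_add``.
    """

    theta_cl: float = 0.29      # L/h per kg^0.75 at reference covariates
    theta_v: float = 1.00       # L/kg
    exp_scr: float = -0.70      # power exponent on sCr/ref_scr
    exp_dflt: float = -0.09     # power exponent on DFLT/ref_dflt
    ref_scr: float = 0.16       # mg/dL (study median)
    ref_dflt: float = 17.0      # days (study median)
    omega_cl: float = 0.4647    # SD of eta_CL
    omega_v: float = 0.4814     # SD of eta_V
    sigma_prop: float = 0.565   # proportional residual SD (fraction)
    sigma_add: float = 0.0      # additive residual SD (ug/mL)
    dflt_floor: float = 1.0     # days; keeps (DFLT/ref)^exp finite at DFLT=0

    def __post_init__(self) -> None:
        if not self.theta_cl > 0:
            raise InvalidInputError(f"theta_cl must be > 0, got {self.theta_cl}")
        if not self.theta_v > 0:
            raise InvalidInputError(f"theta_v must be > 0, got {self.theta_v}")
        for name in ("omega_cl", "omega_v", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise InvalidInputError("sigma_prop and sigma_add cannot both be zero")


@dataclass(frozen=True)
class IndividualParams:
    """Individual clearance (L/h) and volume (L); ``k_e = CL/V`` (1/h)."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not self.cl > 0:
            raise InvalidInputError(f"CL must be > 0, got {self.cl}")
        if not self.v > 0:
            raise InvalidInputError(f"V must be > 0, got {self.v}")

    @property
    def k_e(self) -> float:
        return self.cl / self.v


@dataclass(frozen=True)
class RegimenSpec:
    """An intermittent-infusion dosing regimen in mg/kg."""

    dose_mg_per_kg: float
    interval: float
    infusion_duration: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.dose_mg_per_kg > 0:
            raise InvalidInputError("dose must be > 0 mg/kg")
        if not self.infusion_duration > 0:
            raise InvalidRegimenError("infusion duration must be > 0 h")
        if not self.interval > self.infusion_duration:
            raise InvalidRegimenError(
                f"dosing interval ({self.interval} h) must exceed infusion "
                f"duration ({self.infusion_duration} h)"
            )

    @property
    def daily_dose_mg_per_kg(self) -> float:
        return self.dose_mg_per_kg * 24.0 / self.interval

    def describe(self) -> str:
        return self.label or f"{self.dose_mg_per_kg:g} mg/kg q{self.interval:g}h"


def typical_clearance(cov: CovariateSet, p: PopulationParams) -> float:
    """Typical (population) clearance in L/h at a subject's covariates.

    ``TVCL = theta_cl * wt^0.75 * (sCr/ref_scr)^exp_scr * (DFLT/ref_dflt)^exp_dflt``

    DFLT is floored at ``p.dflt_floor`` (default 1 day) so the power term
    remains finite for same-day transplants (DFLT = 0).
    """
    dflt = max(cov.dflt, p.dflt_floor)
    return (
        p.theta_cl
        * cov.weight**0.75
        * (cov.scr / p.ref_scr) ** p.exp_scr
        * (dflt / p.ref_dflt) ** p.exp_dflt
    )


def typical_volume(cov: CovariateSet, p: PopulationParams) -> float:
    """Typical volume of distribution in L: ``TVV = theta_v * wt``."""
    return p.theta_v * cov.weight


def individual_params(
    cov: CovariateSet, p: PopulationParams, eta_cl: float = 0.0, eta_v: float = 0.0
) -> IndividualParams:
    """Individual parameters with log-normal random effects applied."""
    if not (math.isfinite(eta_cl) and math.isfinite(eta_v)):
        raise InvalidInputError("eta values must be finite")
    return IndividualParams(
        cl=typical_clearance(cov, p) * math.exp(eta_cl),
        v=typical_volume(cov, p) * math.exp(eta_v),
    )


def profile_matrices(
    times: np.ndarray, doses: list[DoseEvent]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute infusion geometry for fast repeated concentration evaluation.

    Returns ``(TE, TD, R)`` with shape ``(n_times, n_doses)``: elapsed
    infusion time, post-infusion decay time, and infusion rate. These depend
    only on the sampling design, not on CL/V, so likelihood code can reuse
    them across parameter values.
    """
    t = np.asarray(times, dtype=float).reshape(-1, 1)
    t0 = np.array([d.start_time for d in doses], dtype=float)
    dur = np.array([d.duration for d in doses], dtype=float)
    rate = np.array([d.rate for d in doses], dtype=float)
    since = t - t0
    te = np.clip(since, 0.0, dur)
    td = np.clip(since - dur, 0.0, None)
    return te, td, np.broadcast_to(rate, te.shape).copy()


def concentration_from_matrices(te, td, rate, cl, v):
    """Superposition concentration given precomputed ``profile_matrices``.

    ``c(t) = sum_doses (R/CL) * (1 - e^{-ke*te}) * e^{-ke*td}``

    ``cl``/``v`` may be scalars or arrays broadcastable against leading axes
    of ``te``; summation is over the trailing (dose) axis.
    """
    ke = cl / v
    return np.sum((rate / cl) * -np.expm1(-ke * te) * np.exp(-ke * td), axis=-1)


def concentration(t, doses: list[DoseEvent], ip: IndividualParams):
    """Serum concentration (ug/mL) at time(s) ``t`` by superposition.

    During an infusion that started at ``t0``:
    ``(R/CL) * (1 - e^{-ke (t-t0)})``; after it ends at ``t1`` the
    accumulated amount decays mono-exponentially. Linear kinetics make the
    multi-dose profile the sum of single-dose profiles. Times before the
    first dose return 0.
    """
    scalar = np.isscalar(t) or np.ndim(t) == 0
    times = np.atleast_1d(np.asarray(t, dtype=float))
    if len(doses) == 0:
        out = np.zeros_like(times)
        return float(out[0]) if scalar else out
    te, td, rate = profile_matrices(times, doses)
    out = concentration_from_matrices(te, td, rate, ip.cl, ip.v)
    return float(out[0]) if scalar else out


def steady_state_trough(reg: RegimenSpec, cov: CovariateSet, ip: IndividualParams) -> float:
    """Closed-form steady-state trough (ug/mL) for a mg/kg regimen.

    ``Cmin,ss = (R/CL) (1 - e^{-ke Tinf}) e^{-ke (tau - Tinf)} / (1 - e^{-ke tau})``
    evaluated immediately before a dose at steady state.
    """
    amount = reg.dose_mg_per_kg * cov.weight
    rate = amount / reg.infusion_duration
    ke = ip.k_e
    tau = reg.interval
    tinf = reg.infusion_duration
    return (
        (rate / ip.cl)
        * -np.expm1(-ke * tinf)
        * math.exp(-ke * (tau - tinf))
        / -np.expm1(-ke * tau)
    )


def auc24_at_steady_state(daily_dose: float, cl: float) -> float:
    """Steady-state 24-h AUC (mg*h/L): ``daily_dose / CL`` for linear kinetics."""
    if not daily_dose > 0:
        raise InvalidInputError(f"daily dose must be > 0, got {daily_dose}")
    if not cl > 0:
        raise InvalidInputError(f"CL must be > 0, got {cl}")
    return daily_dose / cl
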
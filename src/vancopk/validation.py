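"""Bootstrap, visual predictive check and goodness-of-fit diagnostics.

The bootstrap resamples whole subjects (treatment episodes) with
replacement and refits each replicate, warm-started at the original
estimates; percentile summaries over converged replicates give the
nonparametric confidence intervals. The VPC simulates replicate datasets at
the original design (same subjects, doses, sampling times and covariates)
and compares observed percentiles with simulation-based prediction bands in
bins of time-after-dose. Residual diagnostics include population and
individual predictions, IWRES, and conditional weighted residuals (CWRES)
from the standard FOCE first-order expansion about the empirical Bayes
estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .estimation import FitResult, ModelSpec, _Engine, fit
from .pk_core import InvalidInputError, PopulationParams, SubjectRecord

__all__ = [
    "BootstrapResult",
    "VPCResult",
    "GofResult",
    "bootstrap",
    "vpc",
    "gof_diagnostics",
]


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    summary: pd.DataFrame  # parameter, median, ci_lower, ci_upper
    replicates: pd.DataFrame  # per-replicate parameter estimates (converged only)
    low_convergence_warning: bool

    @property
    def convergence_rate(self) -> float:
        return self.n_converged / self.n_requested if self.n_requested else float("nan")


def bootstrap(
    data: list[SubjectRecord],
    spec: ModelSpec,
    fit_result: FitResult,
    n_boot: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap with the subject as the resampling unit.

    Each of ``n_boot`` resamples draws ``len(data)`` subjects with
    replacement and is refitted starting from the original estimates (warm
    start — fast, though it can mask multimodality). Summaries are the
    percentile median and 2.5/97.5 bounds over converged replicates.
    Deterministic given ``seed``.
    """
    if not fit_result.converged:
        raise InvalidInputError("bootstrap requires a converged reference fit")
    rng = np.random.default_rng(seed)
    n = len(data)
    records = []
    n_converged = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = [data[i] for i in idx]
        refit = fit(
            resample,
            spec,
            dict(fit_result.params),
            compute_se=False,
            compute_ebes=False,
            maxiter=0,  # straight to Powell: the warm start is near the optimum
            polish_rounds=1,
            polish_maxiter=1,
        )
        # a light warm-started refit counts as converged when its objective
        # is finite and did not blow up; stationarity to full precision is
        # not demanded of resampling replicates
        if math.isfinite(refit.ofv) and refit.ofv < 1e11:
            n_converged += 1
            records.append(refit.params)
    reps = pd.DataFrame(records)
    rows = []
    for name in fit_result.params:
        if name in reps.columns and len(reps):
            q = np.percentile(reps[name].to_numpy(), [2.5, 50.0, 97.5])
            rows.append(
                {"parameter": name, "median": q[1], "ci_lower": q[0], "ci_upper": q[2]}
            )
        else:
            rows.append(
                {
                    "parameter": name,
                    "median": float("nan"),
                    "ci_lower": float("nan"),
                    "ci_upper": float("nan"),
                }
            )
    low = n_converged < 0.5 * n_boot
    if low:
        warnings.warn(
            f"bootstrap convergence rate {n_converged}/{n_boot} below 50%", RuntimeWarning
        )
    return BootstrapResult(
        n_requested=n_boot,
        n_converged=n_converged,
        summary=pd.DataFrame(rows),
        replicates=reps,
        low_convergence_warning=low,
    )


@dataclass
class VPCResult:
    table: pd.DataFrame  # per-bin observed and simulated percentile bands
    fraction_within_pi: float  # observations inside the pointwise 90% PI
    bin_edges: np.ndarray
    n_sim: int


def _time_after_dose(subject: SubjectRecord) -> np.ndarray:
    dose_times = np.array([d.start_time for d in subject.doses])
    out = []
    for o in subject.observations:
        before = dose_times[dose_times <= o.time]
        out.append(o.time - before[-1] if before.size else o.time)
    return np.array(out)


def _simulate_replicates(engine: _Engine, vals: dict, n_sim: int, rng, floor: float):
    """Simulated observation matrices (n_sim, n_total_obs) at the original design."""
    tvcl, tvv = engine._tv(vals)
    engine._cur_sig = engine._sig(vals)
    om = np.array([vals["omega_cl"], vals["omega_v"]])
    mask = engine.mask
    sims = np.empty((n_sim, int(mask.sum())))
    sa, sp = engine._cur_sig
    for r in range(n_sim):
        eta = rng.normal(0.0, 1.0, size=(engine.n, 2)) * om
        f = engine._predict(tvcl, tvv, eta)[mask]
        if engine.spec.residual_model == "exponential":
            y = f * np.exp(rng.normal(0.0, sa, size=f.shape))
        else:
            y = f * (1.0 + (rng.normal(0.0, sp, size=f.shape) if sp > 0 else 0.0))
            if sa > 0:
                y = y + rng.normal(0.0, sa, size=f.shape)
        sims[r] = np.maximum(y, floor)
    return sims


def vpc(
    data: list[SubjectRecord],
    spec: ModelSpec,
    fit_result: FitResult | PopulationParams,
    n_sim: int = 1000,
    bins: int = 8,
    seed: int | None = None,
    observation_floor: float = 0.1,
) -> VPCResult:
    """Visual predictive check at the original design.

    Bins observations by time after the most recent dose (quantile-spaced
    edges), compares observed 5th/50th/95th percentiles with the 95%
    band of the same percentiles over ``n_sim`` simulated replicates, and
    reports the fraction of observations inside the pointwise simulated 90%
    prediction interval. Empty bins are dropped with a warning.
    """
    engine = _Engine(data, spec)
    if isinstance(fit_result, FitResult):
        vals = dict(fit_result.params)
    else:
        from .estimation import _params_to_values

        vals = _params_to_values(engine, fit_result)
    rng = np.random.default_rng(seed)
    sims = _simulate_replicates(engine, vals, n_sim, rng, observation_floor)

    obs = engine.y[engine.mask]
    tad = np.concatenate([_time_after_dose(s) for s in data])
    lo_pi = np.percentile(sims, 5.0, axis=0)
    hi_pi = np.percentile(sims, 95.0, axis=0)
    frac = float(np.mean((obs >= lo_pi) & (obs <= hi_pi)))

    edges = np.unique(np.quantile(tad, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    rows = []
    pcts = (5.0, 50.0, 95.0)
    for b in range(len(edges) - 1):
        in_bin = idx == b
        if not in_bin.any():
            warnings.warn(f"VPC bin {b} is empty; dropped", RuntimeWarning)
            continue
        row = {
            "bin": b,
            "tad_lo": edges[b],
            "tad_hi": edges[b + 1],
            "tad_mid": float(np.median(tad[in_bin])),
            "n_obs": int(in_bin.sum()),
        }
        for p in pcts:
            row[f"obs_p{int(p)}"] = float(np.percentile(obs[in_bin], p))
        sim_bin = sims[:, in_bin]
        for p in pcts:
            per_rep = np.percentile(sim_bin, p, axis=1)
            lo, med, hi = np.percentile(per_rep, [2.5, 50.0, 97.5])
            row[f"sim_p{int(p)}_lo"] = float(lo)
            row[f"sim_p{int(p)}_med"] = float(med)
            row[f"sim_p{int(p)}_hi"] = float(hi)
        rows.append(row)
    table = pd.DataFrame(rows)
    return VPCResult(table=table, fraction_within_pi=frac, bin_edges=edges, n_sim=n_sim)


@dataclass
class GofResult:
    table: pd.DataFrame
    cwres_mean: float
    cwres_sd: float


def gof_diagnostics(
    data: list[SubjectRecord], spec: ModelSpec, fit_result: FitResult | PopulationParams
) -> GofResult:
    """Per-observation goodness-of-fit quantities.

    PRED is the population prediction (eta = 0), IPRED the individual
    prediction at the EBEs, IWRES the residual standardized by the
    individual residual SD, and CWRES the conditional weighted residual from
    the FOCE linearization about the EBEs (whitened by the full per-subject
    covariance ``G Omega G' + diag(v)``). ``fit_result`` may also be a
    ``PopulationParams`` to diagnose a hypothesised model without fitting.
    """
    engine = _Engine(data, spec)
    if isinstance(fit_result, FitResult):
        vals = dict(fit_result.params)
    else:
        from .estimation import _params_to_values

        vals = _params_to_values(engine, fit_result)
    comps, eta = engine.ofv_components(vals)
    tvcl, tvv = engine._tv(vals)
    engine._cur_sig = engine._sig(vals)

    pred = engine._predict(tvcl, tvv, np.zeros((engine.n, 2)))
    ipred, d1, d2 = engine._predict(tvcl, tvv, eta, grads=True)
    v_ind, _ = engine._resid(ipred)
    if engine.spec.residual_model == "exponential":
        resid = engine.logy - np.log(np.maximum(ipred, 1e-12))
    else:
        resid = engine.y - ipred
    iwres = resid / np.sqrt(v_ind)

    om2 = np.array([vals["omega_cl"], vals["omega_v"]]) ** 2
    rows = []
    for i, s in enumerate(data):
        k = len(s.observations)
        if k == 0:
            continue
        g = np.column_stack([d1[i, :k], d2[i, :k]])
        f_i = ipred[i, :k]
        if engine.spec.residual_model == "exponential":
            # linearize on the log scale, where the residual model is additive
            g = g / f_i[:, None]
            mu = np.log(np.maximum(f_i, 1e-12)) - g @ eta[i]
            y_i = engine.logy[i, :k]
        else:
            mu = f_i - g @ eta[i]
            y_i = engine.y[i, :k]
        cov = g @ np.diag(om2) @ g.T + np.diag(v_ind[i, :k])
        try:
            chol = np.linalg.cholesky(cov)
            cwres = solve_triangular(chol, y_i - mu, lower=True)
        except np.linalg.LinAlgError:
            cwres = (y_i - mu) / np.sqrt(np.diag(cov))
        tad = _time_after_dose(s)
        for j in range(k):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "time": s.observations[j].time,
                    "tad": float(tad[j]),
                    "dv": float(engine.y[i, j]),
                    "pred": float(pred[i, j]),
                    "ipred": float(f_i[j]),
                    "iwres": float(iwres[i, j]),
                    "cwres": float(cwres[j]),
                }
            )
    table = pd.DataFrame(rows)
    return GofResult(
        table=table,
        cwres_mean=float(table["cwres"].mean()),
        cwres_sd=float(table["cwres"].std(ddof=1)),
    )
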
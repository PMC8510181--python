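"""Independent numerical oracles used only by the test suite.

These deliberately avoid the package's own likelihood/profile code paths:
the ODE oracle integrates the one-compartment infusion model with scipy's
initial-value solver, the quadrature oracle evaluates the marginal
likelihood by adaptive Gauss-Hermite quadrature, and the AUC oracle is a
dense trapezoidal integration.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.integrate import solve_ivp
from scipy.optimize import minimize


def ode_concentration(t, doses, cl, v, rtol=1e-10, atol=1e-12):
    """Concentration at times ``t`` by numerically integrating
    dA/dt = R(t) - (CL/V) A, piecewise between infusion breakpoints."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    breaks = sorted({0.0} | {d.start_time for d in doses} | {d.start_time + d.duration for d in doses} | set(t))
    ke = cl / v

    def rate_at(s):
        return sum(d.rate for d in doses if d.start_time <= s < d.start_time + d.duration)

    amounts = {0.0: 0.0}
    a = 0.0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        r = rate_at(0.5 * (t0 + t1))
        sol = solve_ivp(
            lambda s, y: [r - ke * y[0]], (t0, t1), [a], rtol=rtol, atol=atol, dense_output=True
        )
        a = float(sol.y[0, -1])
        amounts[t1] = a
    return np.array([amounts[float(ti)] / v for ti in t])


def trapezoid_auc(times, concentrations):
    return float(np.trapezoid(concentrations, times))


def _subject_m2ll_given_eta(subject, p, eta_cl, eta_v, conc_fn):
    """Exact -2 log p(y | eta) for combined/additive/proportional error."""
    cl = _tvcl(subject, p) * math.exp(eta_cl)
    v = _tvv(subject, p) * math.exp(eta_v)
    total = 0.0
    for obs in subject.observations:
        f = conc_fn(obs.time, subject.doses, cl, v)
        var = p.sigma_add**2 + (p.sigma_prop * f) ** 2
        total += (obs.concentration - f) ** 2 / var + math.log(2.0 * math.pi * var)
    return total


def _tvcl(subject, p):
    c = subject.covariates
    dflt = max(c.dflt, p.dflt_floor)
    return (
        p.theta_cl
        * c.weight**0.75
        * (c.scr / p.ref_scr) ** p.exp_scr
        * (dflt / p.ref_dflt) ** p.exp_dflt
    )


def _tvv(subject, p):
    return p.theta_v * subject.covariates.weight


def _analytic_conc(t, doses, cl, v):
    ke = cl / v
    total = 0.0
    for d in doses:
        since = t - d.start_time
        if since <= 0:
            continue
        te = min(since, d.duration)
        td = max(since - d.duration, 0.0)
        total += (d.rate / cl) * (1.0 - math.exp(-ke * te)) * math.exp(-ke * td)
    return total


def quadrature_ofv(data, p, n_nodes=64):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    For each subject the integrand is centered and scaled at its mode
    (located by Nelder-Mead over the random-effect plane) before applying a
    tensor-product Gauss-Hermite rule with ``n_nodes`` per active dimension.
    """
    nodes, weights = hermegauss(n_nodes)  # probabilists' rule: weight e^{-x^2/2}
    total = 0.0
    for subject in data:
        omegas = [p.omega_cl, p.omega_v]
        active = [k for k in range(2) if omegas[k] > 1e-8]

        def neg_log_joint(eta_active):
            eta = [0.0, 0.0]
            for j, k in enumerate(active):
                eta[k] = eta_active[j]
            val = 0.5 * _subject_m2ll_given_eta(subject, p, eta[0], eta[1], _analytic_conc)
            for k in active:
                val += 0.5 * eta[k] ** 2 / omegas[k] ** 2 + 0.5 * math.log(
                    2.0 * math.pi * omegas[k] ** 2
                )
            return val

        if not active:
            total += 2.0 * neg_log_joint([])
            continue

        d = len(active)
        res = minimize(neg_log_joint, np.zeros(d), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        mode = res.x
        # curvature scaling from a finite-difference Hessian at the mode
        h = 1e-4
        hess = np.zeros((d, d))
        f0 = neg_log_joint(mode)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            hess[i, i] = (neg_log_joint(mode + ei) - 2 * f0 + neg_log_joint(mode - ei)) / h**2
            for j in range(i + 1, d):
                ej = np.zeros(d)
                ej[j] = h
                hess[i, j] = hess[j, i] = (
                    neg_log_joint(mode + ei + ej)
                    - neg_log_joint(mode + ei - ej)
                    - neg_log_joint(mode - ei + ej)
                    + neg_log_joint(mode - ei - ej)
                ) / (4 * h * h)
        scale = np.linalg.cholesky(np.linalg.inv(hess))

        if d == 1:
            pts = mode[0] + scale[0, 0] * nodes
            log_terms = np.array(
                [-neg_log_joint([z]) + 0.5 * u * u for z, u in zip(pts, nodes)]
            )
            log_w = np.log(weights) + log_terms
            m = log_w.max()
            integral = math.log(np.exp(log_w - m).sum()) + m + math.log(abs(scale[0, 0]))
        else:
            uu, vv = np.meshgrid(nodes, nodes, indexing="ij")
            u_flat = np.column_stack([uu.ravel(), vv.ravel()])
            pts = mode + u_flat @ scale.T
            log_terms = np.array(
                [
                    -neg_log_joint(pt) + 0.5 * (u * u).sum()
                    for pt, u in zip(pts, u_flat)
                ]
            )
            log_w = (
                np.log(np.outer(weights, weights).ravel())
                + log_terms
            )
            m = log_w.max()
            integral = (
                math.log(np.exp(log_w - m).sum())
                + m
                + math.log(abs(np.linalg.det(scale)))
            )
        total += -2.0 * integral
    return total


def grid_search_ebe(subject, p, half_width=3.0, n_grid=241):
    """Brute-force conditional-mode search over the (eta_CL, eta_V) plane."""
    grid_cl = np.linspace(-half_width, half_width, n_grid)
    grid_v = np.linspace(-half_width, half_width, n_grid)
    best = (math.inf, 0.0, 0.0)
    for e1 in grid_cl:
        for e2 in grid_v:
            val = 0.5 * _subject_m2ll_given_eta(subject, p, e1, e2, _analytic_conc)
            if p.omega_cl > 0:
                val += 0.5 * e1**2 / p.omega_cl**2
            if p.omega_v > 0:
                val += 0.5 * e2**2 / p.omega_v**2
            if val < best[0]:
                best = (val, e1, e2)
    return best[1], best[2]
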
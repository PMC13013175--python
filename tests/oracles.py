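"""Independent oracles used by the test-suite.

These deliberately avoid the package's closed-form and FOCE code paths:
the concentration oracle integrates the depot/central ODE system with a
stiff solver, and the likelihood oracle evaluates the exact marginal
-2 log-likelihood by adaptive Gauss-Hermite quadrature over the random
effects.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from rivapk.model import ETA_NAMES, ETA_THETA_INDEX, PopModel
from rivapk.pkmodel import IndivParams


def ode_conc(t: float, dose: float, p: IndivParams, rtol: float = 1e-11) -> float:
    """Concentration (µg/L) by piecewise stiff ODE integration of
    depot' = input - ka*depot, central' = ka*depot - ke*central."""
    ke = p.cl_f / p.v_f
    r0 = dose / p.d1
    y = np.zeros(2)
    breaks = [0.0, p.alag1, p.alag1 + p.d1, t]
    segments = sorted({b for b in breaks if 0.0 <= b <= t})
    for a, b in zip(segments[:-1], segments[1:]):
        if b <= a:
            continue
        inp = r0 if (a >= p.alag1 - 1e-12 and b <= p.alag1 + p.d1 + 1e-12) else 0.0

        def rhs(_, state):
            return [inp - p.ka * state[0], p.ka * state[0] - ke * state[1]]

        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=1e-14)
        y = sol.y[:, -1]
    return float(y[1] / p.v_f * 1000.0)


def ode_conc_events(t: float, dose_events, p: IndivParams) -> float:
    """ODE oracle with multiple (time, amount) dosing events, by linearity."""
    return sum(ode_conc(t - td, amt, p) for td, amt in dose_events if td <= t)


def ode_profile(times, dose_events, p: IndivParams, rtol: float = 1e-10):
    """ODE-oracle concentrations at several times with one integration pass
    per dose event (dense output), for the quadrature oracle's inner loop."""
    times = np.asarray(times, float)
    ke = p.cl_f / p.v_f
    out = np.zeros_like(times)
    for td, amt in dose_events:
        tau = times - td
        tmax = float(np.max(tau))
        if tmax <= 0:
            continue
        r0 = amt / p.d1
        y = np.zeros(2)
        vals = {}
        breaks = sorted({0.0, min(p.alag1, tmax), min(p.alag1 + p.d1, tmax), tmax})
        for a, b in zip(breaks[:-1], breaks[1:]):
            if b <= a:
                continue
            inp = r0 if (a >= p.alag1 - 1e-12 and b <= p.alag1 + p.d1 + 1e-12) else 0.0

            def rhs(_, state):
                return [inp - p.ka * state[0], p.ka * state[0] - ke * state[1]]

            inside = [float(x) for x in tau if a < x <= b]
            sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol,
                            atol=1e-14, dense_output=True)
            for x in inside:
                vals[x] = sol.sol(x)[1]
            y = sol.y[:, -1]
        out += np.array([vals.get(float(x), 0.0) if x > 0 else 0.0 for x in tau])
    return out / p.v_f * 1000.0


def exact_marginal_ofv(data, model: PopModel, n_nodes: int = 40) -> float:
    """Exact marginal -2 log-likelihood (without the n*ln(2pi) constant) by
    adaptive Gauss-Hermite quadrature, subject by subject.

    Supports 1-2 active random-effect dimensions (enough for the toy
    datasets it serves).  The structural model is evaluated through the
    package's kernel only via IndivParams/percentile-free closed form — we
    recompute predictions with the ODE oracle to stay fully independent.
    """
    from rivapk.model import individual_params

    obs = data.observations
    doses = data.doses
    active = [i for i, w2 in enumerate(model.omega2) if w2 > 0]
    d = len(active)
    if d > 2:
        raise ValueError("oracle supports at most 2 active eta dimensions")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    total = 0.0
    n_total = 0
    for sid in data.subject_ids:
        y = obs.loc[obs["ID"] == sid, "DV"].to_numpy(float)
        t = obs.loc[obs["ID"] == sid, "TIME"].to_numpy(float)
        if len(y) == 0:
            continue
        n_total += len(y)
        devents = [(row["TIME"], row["AMT"]) for _, row in
                   doses[doses["ID"] == sid].iterrows()]

        def log_integrand(eta_act):
            eta = np.zeros(len(ETA_NAMES))
            for k, i in enumerate(active):
                eta[i] = eta_act[k]
            p = individual_params(model, eta)
            f = ode_profile(t, devents, p)
            v = model.sigma2_prop * f**2 + model.sigma2_add
            ll = -0.5 * np.sum(np.log(2.0 * np.pi * v) + (y - f) ** 2 / v)
            lp = -0.5 * sum(eta_act[k] ** 2 / model.omega2[i]
                            + np.log(2.0 * np.pi * model.omega2[i])
                            for k, i in enumerate(active))
            return ll + lp

        if d == 0:
            total += -2.0 * log_integrand(np.zeros(0))
            continue

        # adaptive: centre the quadrature at the mode, scale by the Hessian
        neg = lambda e: -log_integrand(e)
        res = optimize.minimize(neg, np.zeros(d), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        mode = res.x
        h = 1e-4
        H = np.zeros((d, d))
        f0 = neg(mode)
        for i in range(d):
            ei = np.zeros(d); ei[i] = h
            H[i, i] = (neg(mode + ei) - 2 * f0 + neg(mode - ei)) / h**2
            for j in range(i + 1, d):
                ej = np.zeros(d); ej[j] = h
                H[i, j] = H[j, i] = (neg(mode + ei + ej) - neg(mode + ei - ej)
                                     - neg(mode - ei + ej) + neg(mode - ei - ej)) / (4 * h**2)
        evals, evecs = np.linalg.eigh(H)
        evals = np.maximum(evals, 1e-8)
        A = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T  # H^{-1/2}

        if d == 1:
            zgrid = nodes[:, None]
            w = weights
        else:
            zi, zj = np.meshgrid(nodes, nodes, indexing="ij")
            zgrid = np.column_stack([zi.ravel(), zj.ravel()])
            w = np.outer(weights, weights).ravel()
        log_terms = np.array([
            log_integrand(mode + np.sqrt(2.0) * (A @ z)) + float(z @ z)
            for z in zgrid
        ])
        mx = np.max(log_terms)
        integral = (2.0 ** (d / 2.0)) * np.prod(1.0 / np.sqrt(evals)) * \
            np.sum(w * np.exp(log_terms - mx))
        total += -2.0 * (mx + np.log(integral))
    return total - n_total * np.log(2.0 * np.pi)
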
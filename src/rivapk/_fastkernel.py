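"""Scalar concentration kernel, JIT-compiled when numba is available.

This mirrors :func:`rivapk.pkmodel._conc_kernel` exactly (same closed form,
same confluent-limit guard) but runs as a tight scalar loop over
observation-dose pairs, which is what the estimation engine needs millions
of times during a fit.  The numpy kernel remains the reference
implementation; equality of the two paths is asserted in the test-suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap


@njit(cache=False, fastmath=False, error_model="numpy")
def conc_scalar(t, dose, ka, cl, v, d1, alag):  # pragma: no cover - jitted
    ke = cl / v
    tau = t - alag
    if tau <= 0.0 or dose == 0.0:
        return 0.0
    confluent = abs(ka - ke) < 1e-9 * (ka + ke)
    if d1 <= 0.0:
        s = tau
        if confluent:
            ac = dose * ka * s * np.exp(-ka * s)
        else:
            ac = dose * ka * (np.exp(-ka * s) - np.exp(-ke * s)) / (ke - ka)
    else:
        r0 = dose / d1
        if tau <= d1:
            e_ka = np.exp(-ka * tau)
            e_ke = np.exp(-ke * tau)
            if confluent:
                ac = r0 * ((1.0 - e_ke) / ke - tau * e_ka)
            else:
                ac = r0 * ((1.0 - e_ke) / ke + (e_ka - e_ke) / (ka - ke))
        else:
            e_ka1 = np.exp(-ka * d1)
            e_ke1 = np.exp(-ke * d1)
            if confluent:
                ac1 = r0 * ((1.0 - e_ke1) / ke - d1 * e_ka1)
            else:
                ac1 = r0 * ((1.0 - e_ke1) / ke + (e_ka1 - e_ke1) / (ka - ke))
            ad1 = (r0 / ka) * (1.0 - e_ka1)
            s = tau - d1
            e_ka = np.exp(-ka * s)
            e_ke = np.exp(-ke * s)
            if confluent:
                ac = ac1 * e_ke + ad1 * ka * s * e_ka
            else:
                ac = ac1 * e_ke + ad1 * ka * (e_ka - e_ke) / (ke - ka)
    if ac < 0.0:
        ac = 0.0
    return ac / v * 1000.0


@njit(cache=False, fastmath=False, error_model="numpy")
def pair_conc(t, dose, ka, cl, v, d1, alag, out):  # pragma: no cover - jitted
    for i in range(t.shape[0]):
        out[i] = conc_scalar(t[i], dose[i], ka[i], cl[i], v[i], d1[i], alag[i])


@njit(cache=False, fastmath=False, error_model="numpy")
def subject_objective(eta_act, act_idx, base_p, dt, amt, local, n_obs, y,
                      winv_act, sig2p, sig2a):  # pragma: no cover - jitted
    """Penalised conditional objective of one subject (FOCE inner problem)."""
    p = base_p.copy()
    for k in range(act_idx.shape[0]):
        p[1 + act_idx[k]] *= np.exp(eta_act[k])
    f = np.zeros(n_obs)
    for j in range(dt.shape[0]):
        f[local[j]] += conc_scalar(dt[j], amt[j], p[0], p[1], p[2], p[3], p[4])
    total = 0.0
    for o in range(n_obs):
        v = sig2p * f[o] * f[o] + sig2a
        if v < 1e-12:
            v = 1e-12
        r = y[o] - f[o]
        total += np.log(v) + r * r / v
    for k in range(act_idx.shape[0]):
        total += eta_act[k] * eta_act[k] * winv_act[k]
    return total


@njit(cache=False, fastmath=False, error_model="numpy")
def polish_eta(eta0, act_idx, base_p, dt, amt, local, n_obs, y, winv_act,
               sig2p, sig2a, h0, tol, max_eval):  # pragma: no cover - jitted
    """Compass (pattern) search refinement of one subject's conditional mode.

    Derivative-free and kink-tolerant: the inner objective is only piecewise
    smooth in the lag/duration random effects.
    """
    d = eta0.shape[0]
    eta = eta0.copy()
    best = subject_objective(eta, act_idx, base_p, dt, amt, local, n_obs, y,
                             winv_act, sig2p, sig2a)
    h = h0
    n_eval = 0
    while h > tol and n_eval < max_eval:
        improved = False
        for k in range(d):
            for s in (-1.0, 1.0):
                trial = eta.copy()
                trial[k] = eta[k] + s * h
                val = subject_objective(trial, act_idx, base_p, dt, amt, local,
                                        n_obs, y, winv_act, sig2p, sig2a)
                n_eval += 1
                if val < best - 1e-13:
                    best = val
                    eta = trial
                    improved = True
        if not improved:
            h *= 0.5
    return eta, best


def pair_conc_eval(t, dose, ka, cl, v, d1, alag) -> np.ndarray:
    """Elementwise concentration for flat pair arrays (all same length)."""
    if HAVE_NUMBA:
        out = np.empty(t.shape[0])
        pair_conc(t, dose, ka, cl, v, d1, alag, out)
        return out
    from .pkmodel import _conc_kernel  # vectorised fallback

    return _conc_kernel(t, dose, ka, cl, v, d1, alag)
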
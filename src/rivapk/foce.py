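"""First-order conditional estimation with interaction (FOCE-I).

The marginal likelihood of each subject's observations is approximated by
linearising the structural model around the subject's conditional mode
(empirical Bayes estimate) of the random effects, while the residual
variance is evaluated at the *individual* prediction (the "interaction").
With ``G = df/deta`` at the mode ``eta_hat`` and ``v`` the residual
variances there, the subject contributes

    OFV_i = ln det V_i + r_i' V_i^{-1} r_i,
    V_i   = diag(v_i) + G_i Omega G_i',
    r_i   = y_i - f_i(eta_hat) + G_i eta_hat,

and the total objective function value (OFV) is the sum over subjects — a
-2 log-likelihood without the n*ln(2pi) constant, the scale on which
likelihood-ratio differences such as 6.63 / 10.83 are read.

The inner problem (the conditional mode) minimises

    sum_j [ ln v_ij(eta) + (y_ij - f_ij(eta))^2 / v_ij(eta) ] + eta' Omega^{-1} eta

per subject; it is solved for all subjects simultaneously by a damped
Gauss-Newton iteration with finite-difference model sensitivities, and warm
started across outer iterations.  The outer problem optimises log-transformed
fixed effects, IIV variances and residual components (covariate coefficients
enter untransformed) with a quasi-Newton method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .covariates import CovariateEffect
from .events import EventTable
from ._fastkernel import pair_conc_eval, polish_eta, subject_objective
from .model import ETA_NAMES, THETA_NAMES, PopModel

__all__ = ["FitResult", "FoceEngine", "foce_ofv", "map_etas", "fit_foce",
           "cwres", "aic", "bic"]

_PENALTY = 1e10
_V_FLOOR = 1e-12


@dataclass
class FitResult:
    """Estimated model with fit diagnostics.

    ``etas`` holds one row per subject with at least one observation
    (empirical Bayes estimates, ETA_NAMES columns).  ``se`` maps estimated
    parameter names to asymptotic (Hessian-based) standard errors on the
    natural scale; it is None when the covariance step was skipped or failed.
    """

    model: PopModel
    ofv: float
    etas: pd.DataFrame
    converged: bool
    n_obs: int
    n_subjects: int
    n_params: int
    param_names: tuple
    estimates: dict | None = None
    se: dict | None = None
    cov: np.ndarray | None = None
    message: str = ""

    def summary(self) -> pd.DataFrame:
        """Estimate / SE / RSE% / 95% CI table over the estimated
        parameters (Wald intervals from the Hessian-based SEs)."""
        rows = []
        for name in self.param_names:
            est = self.estimates[name]
            se = self.se.get(name, np.nan) if self.se else np.nan
            rows.append({"parameter": name, "estimate": est, "se": se,
                         "rse_percent": 100.0 * se / abs(est) if se == se else np.nan,
                         "ci95_lo": est - 1.959964 * se if se == se else np.nan,
                         "ci95_hi": est + 1.959964 * se if se == se else np.nan})
        return pd.DataFrame(rows)


def _effect_free_params(eff: CovariateEffect, cov_values: np.ndarray):
    """(n_free, level order) of an effect; categorical multipliers are
    optimised on the log scale (one per non-reference level)."""
    if eff.form in ("power", "linear"):
        return 1, None
    levels = sorted({str(v) for v in cov_values})
    ref = str(eff.reference) if eff.reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} absent from covariate {eff.covariate!r}")
    return len(levels) - 1, [lv for lv in levels if lv != ref]


class FoceEngine:
    """Compiled design (dose/observation pairs) plus the FOCE-I machinery.

    The engine pre-extracts flat arrays from the event table once; every
    model evaluation is then a vectorised pass over observation-dose pairs,
    which keeps the nested optimisation cheap enough for bootstrap and
    simulation studies.
    """

    def __init__(self, data: EventTable, template: PopModel):
        self.template = template
        obs = data.observations
        doses = data.doses
        ids = list(data.subject_ids)
        self.subject_ids = np.array(ids)
        index = {sid: k for k, sid in enumerate(ids)}
        self.n_subj = len(ids)
        self.y = obs["DV"].to_numpy(float)
        self.t_obs = obs["TIME"].to_numpy(float)
        self.obs_subj = np.array([index[s] for s in obs["ID"]], dtype=int)
        self.n_obs = len(self.y)

        pair_obs, pair_subj, pair_dt, pair_amt = [], [], [], []
        for j, (sid, t) in enumerate(zip(obs["ID"].to_numpy(), self.t_obs)):
            sub_doses = doses[doses["ID"] == sid]
            for _, drow in sub_doses.iterrows():
                if drow["TIME"] <= t:
                    pair_obs.append(j)
                    pair_subj.append(index[sid])
                    pair_dt.append(t - drow["TIME"])
                    pair_amt.append(drow["AMT"])
        self.pair_obs = np.array(pair_obs, dtype=int)
        self.pair_subj = np.array(pair_subj, dtype=int)
        self.pair_dt = np.array(pair_dt, dtype=float)
        self.pair_amt = np.array(pair_amt, dtype=float)

        self.obs_count = np.bincount(self.obs_subj, minlength=self.n_subj)
        self.has_obs = self.obs_count > 0

        # per-subject contiguous views for the scalar (straggler) code path
        self._subj_data = []
        for i in range(self.n_subj):
            pidx = np.flatnonzero(self.pair_subj == i)
            oidx = np.flatnonzero(self.obs_subj == i)
            local = np.searchsorted(oidx, self.pair_obs[pidx]).astype(np.int64)
            self._subj_data.append((np.ascontiguousarray(self.pair_dt[pidx]),
                                    np.ascontiguousarray(self.pair_amt[pidx]),
                                    local, len(oidx),
                                    np.ascontiguousarray(self.y[oidx])))

        # covariate values per subject for each effect
        cov_table = data.covariates() if template.covariate_effects else None
        self.effect_values = []
        self.effect_free = []
        for eff in template.covariate_effects:
            if eff.covariate not in (cov_table.columns if cov_table is not None else ()):
                raise KeyError(f"covariate {eff.covariate!r} not present in the dataset")
            vals = cov_table.loc[ids, eff.covariate].to_numpy()
            self.effect_values.append(vals)
            self.effect_free.append(_effect_free_params(eff, vals))

        # current parameter state
        self.set_params(np.array(template.theta), np.array(template.omega2),
                        template.sigma2_prop, template.sigma2_add,
                        self._template_betas())
        self._warm_etas = np.zeros((self.n_subj, len(ETA_NAMES)))

    # -- parameter state --------------------------------------------------
    def _template_betas(self):
        betas = []
        for eff, (nfree, levels) in zip(self.template.covariate_effects, self.effect_free):
            if eff.form in ("power", "linear"):
                betas.append(np.array([float(eff.theta_cov)]))
            else:
                table = eff.theta_cov if isinstance(eff.theta_cov, dict) else {}
                betas.append(np.log(np.array([float(table.get(lv, 1.0)) for lv in levels])))
        return betas

    def set_params(self, theta, omega2, sig2p, sig2a, betas) -> bool:
        """Install a parameter state; returns False when covariate effects
        produce non-positive multipliers (invalid region, to be penalised)."""
        self.theta = np.asarray(theta, float)
        self.omega2 = np.asarray(omega2, float)
        self.sig2p = float(sig2p)
        self.sig2a = float(sig2a)
        self.betas = betas
        mult = np.ones((self.n_subj, len(THETA_NAMES)))
        for eff, vals, beta, (nfree, levels) in zip(
                self.template.covariate_effects, self.effect_values,
                self.betas, self.effect_free):
            idx = THETA_NAMES.index(eff.target_param)
            if eff.form == "power":
                m = (np.asarray(vals, float) / eff.cov_median) ** beta[0]
            elif eff.form == "linear":
                m = 1.0 + beta[0] * (np.asarray(vals, float) - eff.cov_median) / eff.cov_median
                if np.any(m <= 0.0):
                    return False
            else:
                lut = dict(zip(levels, np.exp(beta)))
                m = np.array([lut.get(str(v), 1.0) for v in vals])
            mult[:, idx] *= m
        self.base_params = self.theta[None, :] * mult  # (n_subj, 5)
        self.active = self.omega2 > 0.0
        return True

    # -- model evaluation --------------------------------------------------
    def _predict_stack(self, etas_stack: np.ndarray) -> np.ndarray:
        """Predictions for a batch of eta matrices: (B, n_subj, 4) -> (B, n_obs).

        One flat kernel call serves the whole batch, which keeps the cost of
        finite-difference sensitivities close to a single evaluation.
        """
        B = etas_stack.shape[0]
        p = np.repeat(self.base_params[None, :, :], B, axis=0)
        p[:, :, 1:5] *= np.exp(etas_stack)
        ps = p[:, self.pair_subj, :].reshape(-1, 5)
        t = np.tile(self.pair_dt, B)
        amt = np.tile(self.pair_amt, B)
        conc = pair_conc_eval(t, amt, ps[:, 0], ps[:, 1], ps[:, 2], ps[:, 3], ps[:, 4])
        obs_idx = (np.arange(B)[:, None] * self.n_obs + self.pair_obs[None, :]).ravel()
        return np.bincount(obs_idx, weights=conc,
                           minlength=B * self.n_obs).reshape(B, self.n_obs)

    def predict(self, etas: np.ndarray) -> np.ndarray:
        """Predicted concentration per observation for per-subject ``etas``
        (shape (n_subj, 4), ETA_NAMES order)."""
        return self._predict_stack(etas[None, :, :])[0]

    def _variance(self, f: np.ndarray) -> np.ndarray:
        return np.maximum(self.sig2p * f**2 + self.sig2a, _V_FLOOR)

    def _indiv_objective(self, etas: np.ndarray) -> np.ndarray:
        """Per-subject penalised conditional objective at ``etas``."""
        f = self.predict(etas)
        v = self._variance(f)
        terms = np.log(v) + (self.y - f) ** 2 / v
        obj = np.bincount(self.obs_subj, weights=terms, minlength=self.n_subj)
        act = self.active
        if act.any():
            obj = obj + np.sum(etas[:, act] ** 2 / self.omega2[act], axis=1)
        return obj

    def _predict_with_jac(self, etas: np.ndarray, h: float = 1e-4):
        """f and its central-difference Jacobian w.r.t. the active etas."""
        act_idx = np.flatnonzero(self.active)
        na = len(act_idx)
        stack = np.repeat(etas[None, :, :], 1 + 2 * na, axis=0)
        for k, dim in enumerate(act_idx):
            stack[1 + 2 * k, :, dim] += h
            stack[2 + 2 * k, :, dim] -= h
        out = self._predict_stack(stack)
        f = out[0]
        J = np.empty((self.n_obs, na))
        for k in range(na):
            J[:, k] = (out[1 + 2 * k] - out[2 + 2 * k]) / (2.0 * h)
        return f, J

    # -- inner problem: conditional modes ----------------------------------
    def estimate_etas(self, etas0: np.ndarray | None = None,
                      gtol: float = 1e-6, max_iter: int = 8):
        """Conditional modes for all subjects by damped Gauss-Newton.

        Subjects without observations keep eta = 0 (the prior mode), as do
        the eta dimensions without IIV.
        """
        na = int(self.active.sum())
        etas = np.zeros((self.n_subj, len(ETA_NAMES)))
        if na == 0:
            return etas
        if etas0 is not None:
            etas[:, self.active] = etas0[:, self.active]
        etas[~self.has_obs] = 0.0
        act = np.flatnonzero(self.active)
        winv = 1.0 / self.omega2[act]
        lam = np.full(self.n_subj, 1e-4)
        obj = self._indiv_objective(etas)
        eye = np.eye(na)
        open_subj = self.has_obs.copy()  # subjects still iterating
        for _ in range(max_iter):
            f, J = self._predict_with_jac(etas)
            v = self._variance(f)
            r = self.y - f
            dv = 2.0 * self.sig2p * f[:, None] * J  # (n_obs, na)
            gobs = dv / v[:, None] * (1.0 - (r**2 / v)[:, None]) - 2.0 * (r / v)[:, None] * J
            grad = np.zeros((self.n_subj, na))
            np.add.at(grad, self.obs_subj, gobs)
            grad += 2.0 * etas[:, act] * winv[None, :]
            grad[~self.has_obs] = 0.0
            open_subj &= np.max(np.abs(grad), axis=1) >= gtol
            if not open_subj.any():
                break
            hobs = (2.0 * np.einsum("oi,oj->oij", J, J) / v[:, None, None]
                    + np.einsum("oi,oj->oij", dv, dv) / (v**2)[:, None, None])
            H = np.zeros((self.n_subj, na, na))
            np.add.at(H, self.obs_subj, hobs)
            H += 2.0 * np.diag(winv)[None, :, :]
            step = -np.linalg.solve(H + lam[:, None, None] * eye[None, :, :], grad[:, :, None])[:, :, 0]
            trial = etas.copy()
            trial[:, act] = np.where(open_subj[:, None], etas[:, act] + step, etas[:, act])
            obj_new = self._indiv_objective(trial)
            improved = (obj_new <= obj + 1e-12) & open_subj
            gain = np.where(improved, obj - obj_new, np.inf)
            etas[improved] = trial[improved]
            obj = np.where(improved, obj_new, obj)
            lam = np.where(improved, np.maximum(lam / 3.0, 1e-6),
                           np.where(open_subj, lam * 10.0, lam))
            # a subject is done when its step no longer buys objective, or
            # damping has grown past any useful step size
            open_subj &= ~(improved & (gain < 1e-9))
            open_subj &= lam <= 1e7
            if not open_subj.any():
                break
        # stragglers: subjects whose conditional objective has a kink (a
        # phase boundary crossing an observation time) defeat Gauss-Newton;
        # polish them individually with a derivative-free compass search
        act_idx = act.astype(np.int64)
        winv_full = 1.0 / self.omega2[act]
        for i in np.flatnonzero(open_subj):
            dt, amt, local, n_obs_i, y_i = self._subj_data[i]
            eta_i, val = polish_eta(etas[i, act].copy(), act_idx,
                                    self.base_params[i].copy(), dt, amt, local,
                                    n_obs_i, y_i, winv_full, self.sig2p,
                                    self.sig2a, 0.05, 1e-6, 2000)
            if val <= obj[i]:
                etas[i, act] = eta_i
        return etas

    def _subject_objective(self, i: int, eta_act: np.ndarray) -> float:
        """Penalised conditional objective of subject ``i`` alone."""
        act = np.flatnonzero(self.active).astype(np.int64)
        dt, amt, local, n_obs_i, y_i = self._subj_data[i]
        return float(subject_objective(
            np.asarray(eta_act, float), act, self.base_params[i].copy(),
            dt, amt, local, n_obs_i, y_i, 1.0 / self.omega2[act],
            self.sig2p, self.sig2a))

    # -- FOCE-I objective ---------------------------------------------------
    def ofv(self, etas: np.ndarray | None = None, warm: bool = True) -> float:
        """FOCE-I objective function value at the current parameter state."""
        if etas is None:
            etas = self.estimate_etas(self._warm_etas if warm else None)
            self._warm_etas = etas
        f, J = self._predict_with_jac(etas)
        v = self._variance(f)
        act = np.flatnonzero(self.active)
        omega_act = self.omega2[act]
        total = 0.0
        for i in np.flatnonzero(self.has_obs):
            sel = self.obs_subj == i
            vi = v[sel]
            ri = self.y[sel] - f[sel]
            if act.size:
                G = J[sel]
                Vi = np.diag(vi) + (G * omega_act[None, :]) @ G.T
                ri = ri + G @ etas[i, act]
            else:
                Vi = np.diag(vi)
            sign, logdet = np.linalg.slogdet(Vi)
            if sign <= 0:
                return float("inf")
            total += logdet + float(ri @ np.linalg.solve(Vi, ri))
        return float(total)

    def cwres(self, etas: np.ndarray) -> np.ndarray:
        """Conditional weighted residuals from the FOCE linearisation."""
        f, J = self._predict_with_jac(etas)
        v = self._variance(f)
        act = np.flatnonzero(self.active)
        omega_act = self.omega2[act]
        out = np.full(self.n_obs, np.nan)
        for i in np.flatnonzero(self.has_obs):
            sel = np.flatnonzero(self.obs_subj == i)
            vi = v[sel]
            ri = self.y[sel] - f[sel]
            if act.size:
                G = J[sel]
                Vi = np.diag(vi) + (G * omega_act[None, :]) @ G.T
                ri = ri + G @ etas[i, act]
            else:
                Vi = np.diag(vi)
            w, Q = np.linalg.eigh(Vi)
            if np.any(w <= 0):
                raise np.linalg.LinAlgError("singular FOCE covariance in CWRES")
            out[sel] = Q @ ((Q.T @ ri) / np.sqrt(w))
        return out


# -- parameter packing ------------------------------------------------------

class _Packer:
    """Maps between the outer optimisation vector and model parameters.

    Positive parameters (typical values, IIV variances, residual components,
    categorical multipliers) are optimised on the log scale; continuous
    covariate coefficients enter untransformed.
    """

    def __init__(self, engine: FoceEngine, model: PopModel, fixed=()):
        fixed = set(fixed)
        self.model = model
        self.engine = engine
        self.entries = []  # (name, kind, index, log?)
        for i, n in enumerate(THETA_NAMES):
            if n not in fixed:
                self.entries.append((n, "theta", i, True))
        for i, n in enumerate(ETA_NAMES):
            if model.omega2[i] > 0 and f"omega2_{n}" not in fixed:
                self.entries.append((f"omega2_{n}", "omega2", i, True))
        if model.sigma2_prop > 0 and "sigma_prop" not in fixed:
            self.entries.append(("sigma_prop", "sig2p", 0, True))
        if model.sigma2_add > 0 and "sigma_add" not in fixed:
            self.entries.append(("sigma_add", "sig2a", 0, True))
        for e_idx, (eff, (nfree, levels)) in enumerate(
                zip(model.covariate_effects, engine.effect_free)):
            base = f"beta_{eff.covariate}_{eff.target_param}"
            if base in fixed:
                continue
            if eff.form in ("power", "linear"):
                self.entries.append((base, "beta", (e_idx, 0), False))
            else:
                for k, lv in enumerate(levels):
                    self.entries.append((f"{base}_{lv}", "beta", (e_idx, k), True))
        self.names = tuple(e[0] for e in self.entries)

    def x0(self) -> np.ndarray:
        m = self.model
        betas = self.engine._template_betas()
        out = []
        for name, kind, idx, logscale in self.entries:
            if kind == "theta":
                val = np.log(m.theta[idx])
            elif kind == "omega2":
                val = np.log(m.omega2[idx])
            elif kind == "sig2p":
                val = np.log(m.sigma2_prop)
            elif kind == "sig2a":
                val = np.log(m.sigma2_add)
            else:
                e_idx, k = idx
                val = betas[e_idx][k]  # categorical betas already log-scale
            out.append(val)
        return np.asarray(out, float)

    def apply(self, x: np.ndarray) -> bool:
        """Install vector ``x`` into the engine; False if invalid region."""
        m = self.model
        theta = np.array(m.theta, float)
        omega2 = np.array(m.omega2, float)
        sig2p, sig2a = m.sigma2_prop, m.sigma2_add
        betas = self.engine._template_betas()
        for (name, kind, idx, logscale), val in zip(self.entries, x):
            if kind == "theta":
                theta[idx] = np.exp(val)
            elif kind == "omega2":
                omega2[idx] = np.exp(val)
            elif kind == "sig2p":
                sig2p = np.exp(val)
            elif kind == "sig2a":
                sig2a = np.exp(val)
            else:
                e_idx, k = idx
                betas[e_idx][k] = val
        return self.engine.set_params(theta, omega2, sig2p, sig2a, betas)

    def to_model(self, x: np.ndarray) -> PopModel:
        self.apply(x)
        eng = self.engine
        m = self.model
        # residual components back on the model's declared scale
        sigma_prop = eng.sig2p if m.prop_is_variance else float(np.sqrt(eng.sig2p))
        sigma_add = float(np.sqrt(eng.sig2a)) if m.add_is_sd else eng.sig2a
        effects = []
        for eff, beta, (nfree, levels) in zip(
                m.covariate_effects, eng.betas, eng.effect_free):
            if eff.form in ("power", "linear"):
                effects.append(replace(eff, theta_cov=float(beta[0])))
            else:
                effects.append(replace(
                    eff, theta_cov={lv: float(np.exp(b)) for lv, b in zip(levels, beta)}))
        return replace(m, theta=tuple(eng.theta), omega2=tuple(eng.omega2),
                       sigma_prop=sigma_prop, sigma_add=sigma_add,
                       covariate_effects=tuple(effects))

    def natural(self, x: np.ndarray) -> np.ndarray:
        """Estimates on the natural scale, in ``self.names`` order."""
        out = []
        for (name, kind, idx, logscale), val in zip(self.entries, x):
            out.append(np.exp(val) if logscale else val)
        return np.asarray(out)


# -- public operations -------------------------------------------------------

def foce_ofv(data: EventTable, model: PopModel) -> float:
    """FOCE-I objective function value of ``model`` on ``data``.

    Subjects without observations contribute nothing.
    """
    return FoceEngine(data, model).ofv(warm=False)


def map_etas(data: EventTable, model: PopModel) -> pd.DataFrame:
    """Empirical Bayes estimates (conditional modes) per subject.

    Returns one row per subject with >= 1 observation, columns ETA_NAMES.
    """
    engine = FoceEngine(data, model)
    etas = engine.estimate_etas()
    keep = engine.has_obs
    return pd.DataFrame(etas[keep], columns=list(ETA_NAMES),
                        index=pd.Index(engine.subject_ids[keep], name="ID"))


def fit_foce(data: EventTable, init: PopModel, fixed=(), compute_se: bool = True,
             maxiter: int = 150, ftol_rel: float = 1e-6,
             polish: bool = True) -> FitResult:
    """Estimate a population model by nested FOCE-I optimisation.

    The outer problem runs a quasi-Newton (L-BFGS-B) pass on transformed
    parameters, optionally followed by a Nelder-Mead polish (``polish=True``)
    that guards against finite-difference noise from the inner problem.
    ``fixed`` names parameters held at their initial values (e.g. ``"ka"``,
    ``"omega2_cl_f"``, ``"sigma_add"``, ``"beta_WT_cl_f"``).

    Non-convergence is reported, not raised: the result carries
    ``converged=False`` with the best parameters found (bootstrap replicates
    count on this behaviour).
    """
    engine = FoceEngine(data, init)
    if not engine.has_obs.any():
        raise ValueError("no usable observations in the dataset")
    packer = _Packer(engine, init, fixed)
    x0 = packer.x0()

    evals = {"n": 0}

    def objective(x):
        evals["n"] += 1
        if np.any(np.abs(x) > 30.0):
            return _PENALTY + float(np.sum(x**2))
        if not packer.apply(x):
            return _PENALTY
        val = engine.ofv()
        if not np.isfinite(val):
            return _PENALTY
        return val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-4, "eps": 1e-4})
        best_x, best_f = res.x, res.fun
        if polish:
            # alternate Powell sweeps (which mop up finite-difference noise
            # from the nested inner problem) with fresh quasi-Newton passes
            # until the OFV stops improving; this recovers the same minimum
            # from dispersed starting points
            for _ in range(4):
                prev = best_f
                res2 = optimize.minimize(objective, best_x, method="Powell",
                                         options={"maxiter": 8, "xtol": 1e-3,
                                                  "ftol": ftol_rel})
                if res2.fun < best_f:
                    best_x, best_f = res2.x, res2.fun
                res3 = optimize.minimize(objective, best_x, method="L-BFGS-B",
                                         options={"maxiter": maxiter, "ftol": 1e-11,
                                                  "gtol": 1e-4, "eps": 1e-4})
                if res3.fun < best_f:
                    best_x, best_f = res3.x, res3.fun
                if prev - best_f < 0.05:
                    break

    converged = bool(np.isfinite(best_f) and best_f < _PENALTY / 2)
    model = packer.to_model(best_x)
    packer.apply(best_x)
    etas = engine.estimate_etas(engine._warm_etas)
    engine._warm_etas = etas
    keep = engine.has_obs
    etas_df = pd.DataFrame(etas[keep], columns=list(ETA_NAMES),
                           index=pd.Index(engine.subject_ids[keep], name="ID"))

    se = cov_nat = None
    if compute_se and converged:
        se, cov_nat = _hessian_se(objective, best_x, packer)

    estimates = dict(zip(packer.names, packer.natural(best_x)))
    return FitResult(model=model, ofv=float(best_f), etas=etas_df,
                     converged=converged, n_obs=engine.n_obs,
                     n_subjects=int(keep.sum()), n_params=len(x0),
                     param_names=packer.names, estimates=estimates,
                     se=se, cov=cov_nat, message=str(res.message))


def _hessian_se(objective, x, packer: _Packer, step: float = 1e-3):
    """Asymptotic SEs from the finite-difference Hessian of the OFV.

    OFV is a -2 log-likelihood, so cov = 2 * H^{-1}; delta method maps the
    transformed scale back to natural units.
    """
    n = len(x)
    H = np.empty((n, n))
    f0 = objective(x)
    fp = np.empty(n); fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n); e[i] = step
        fp[i] = objective(x + e)
        fm[i] = objective(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            fpp = objective(x + ei + ej)
            fmm = objective(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm) / (2.0 * step**2)
    try:
        cov_x = 2.0 * np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return None, None
    nat = packer.natural(x)
    grad = np.array([nat[i] if packer.entries[i][3] else 1.0 for i in range(n)])
    cov_nat = cov_x * np.outer(grad, grad)
    var = np.diag(cov_nat)
    # parameters at a boundary (e.g. a variance collapsing to zero) make the
    # Hessian indefinite in their direction; report NaN there, not nothing
    se = {name: float(np.sqrt(v)) if v >= 0 else float("nan")
          for name, v in zip(packer.names, var)}
    return se, cov_nat


def cwres(fit: FitResult, data: EventTable) -> pd.DataFrame:
    """Conditional weighted residuals of a converged fit, one row per
    observation (ID, TIME, DV, CWRES)."""
    if not fit.converged:
        raise ValueError("cwres requires a converged fit")
    engine = FoceEngine(data, fit.model)
    etas = np.zeros((engine.n_subj, len(ETA_NAMES)))
    for k, sid in enumerate(engine.subject_ids):
        if sid in fit.etas.index:
            etas[k] = fit.etas.loc[sid].to_numpy()
    etas = engine.estimate_etas(etas)
    res = engine.cwres(etas)
    obs = data.observations
    return pd.DataFrame({"ID": obs["ID"].to_numpy(), "TIME": obs["TIME"].to_numpy(),
                         "DV": obs["DV"].to_numpy(), "CWRES": res})


def aic(fit: FitResult) -> float:
    """Akaike information criterion on the OFV scale: OFV + 2p."""
    return fit.ofv + 2.0 * fit.n_params


def bic(fit: FitResult) -> float:
    """Bayesian information criterion on the OFV scale: OFV + p*ln(n_obs)."""
    return fit.ofv + fit.n_params * np.log(fit.n_obs)
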
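"""Covariate machinery: functional forms, derived clinical covariates, and the
stepwise forward-inclusion / backward-elimination covariate search.

Continuous covariates act on a PK parameter through median-centred power or
linear forms, ``P_i = P_pop * (cov_i/cov_m)**theta`` or
``P_i = P_pop * (1 + theta*(cov_i - cov_m)/cov_m)``; categorical covariates
apply one multiplier per non-reference level.  Model selection follows the
classical stepwise likelihood-ratio scheme: forward inclusion at
dOFV > 6.63 (chi-square, 1 df, p < 0.01) and backward elimination at
dOFV > 10.83 (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateEffect",
    "cockcroft_gault",
    "covariate_multiplier",
    "forward_select",
    "backward_eliminate",
    "SelectionResult",
    "FORWARD_DOFV",
    "BACKWARD_DOFV",
]

#: forward-inclusion threshold: chi-square(1) quantile at p = 0.01
FORWARD_DOFV = 6.63
#: backward-elimination threshold: chi-square(1) quantile at p = 0.001
BACKWARD_DOFV = 10.83


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    ``theta_cov`` is the effect coefficient: the exponent for the power form,
    the slope for the linear form, or a mapping level -> multiplier for the
    categorical form (the reference level is implicit with multiplier 1).
    ``cov_median`` is the centering value and is required for the continuous
    forms.
    """

    target_param: str  # one of ka, cl_f, v_f, d1, alag1
    covariate: str
    form: str  # "power" | "linear" | "categorical"
    theta_cov: float | dict = 0.0
    cov_median: float | None = None
    reference: str | None = None  # categorical only

    def __post_init__(self) -> None:
        if self.form not in ("power", "linear", "categorical"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form in ("power", "linear"):
            if self.cov_median is None or self.cov_median <= 0:
                raise ValueError(
                    f"{self.form} form on {self.covariate!r} needs cov_median > 0"
                )

    @property
    def label(self) -> str:
        return f"{self.covariate}~{self.target_param}({self.form})"


def covariate_multiplier(effect: CovariateEffect, value):
    """Dimensionless multiplier this effect applies for covariate ``value``.

    Returns exactly 1.0 at the centering value for the continuous forms and
    for the reference level of a categorical effect.
    """
    if effect.form == "power":
        return (np.asarray(value, float) / effect.cov_median) ** effect.theta_cov
    if effect.form == "linear":
        mult = 1.0 + effect.theta_cov * (np.asarray(value, float) - effect.cov_median) / effect.cov_median
        if np.any(mult <= 0.0):
            raise ValueError(
                f"linear covariate effect {effect.label} yields non-positive "
                f"parameter multiplier for value {value!r}"
            )
        return mult
    # categorical
    table = effect.theta_cov if isinstance(effect.theta_cov, dict) else {}
    values = np.atleast_1d(np.asarray(value, dtype=object))
    mult = np.array([float(table.get(v, 1.0)) for v in values])
    return mult if np.ndim(value) else float(mult[0])


def cockcroft_gault(age, weight, scr, sex):
    """Cockcroft-Gault creatinine clearance (mL/min).

    Parameters
    ----------
    age : years (0 < age < 140)
    weight : actual body weight, kg
    scr : serum creatinine, µmol/L (divided by 88.4 to convert to mg/dL)
    sex : "M"/"male" or "F"/"female" (case-insensitive); arrays allowed

    CrCl = (140 - age) * weight / (72 * SCr/88.4), times 0.85 for females.
    """
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(age <= 0.0) or np.any(age >= 140.0):
        raise ValueError("age must lie in (0, 140) years")
    if np.any(weight <= 0.0) or np.any(scr <= 0.0):
        raise ValueError("weight and serum creatinine must be positive")
    scalar = age.ndim == 0 and np.ndim(sex) == 0
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    female = np.array([str(s).strip().lower() in ("f", "female") for s in sex_arr])
    crcl = (140.0 - age) * weight / (72.0 * scr / 88.4)
    crcl = crcl * np.where(female, 0.85, 1.0)
    return float(crcl[0]) if scalar else crcl


@dataclass
class SelectionResult:
    """Outcome of a stepwise covariate search."""

    final: object  # FitResult of the selected model
    trace: pd.DataFrame  # step, candidate, delta_ofv, converged, decision


def _fit_with_effects(data, model, effects, fit_kwargs):
    from .foce import fit_foce  # deferred to avoid an import cycle

    init = replace(model, covariate_effects=tuple(effects))
    return fit_foce(data, init, **fit_kwargs)


def forward_select(data, base, candidates: Sequence[CovariateEffect],
                   threshold: float = FORWARD_DOFV, **fit_kwargs) -> SelectionResult:
    """Forward stepwise inclusion of covariate effects.

    At each step every remaining candidate is added (alone) to the current
    model and refitted; the candidate with the largest OFV drop is kept if
    that drop exceeds ``threshold`` (default 6.63, i.e. p < 0.01 on 1 df).
    The search stops when no candidate qualifies.  Candidates whose fit does
    not converge are recorded and skipped for that step.  Ties are broken by
    candidate order.
    """
    if not base.converged:
        raise ValueError("forward_select requires a converged base fit")
    fit_kwargs.setdefault("compute_se", False)
    current = base
    remaining = list(candidates)
    rows = []
    step = 0
    while remaining:
        step += 1
        best = None
        results = []
        for cand in remaining:
            effects = list(current.model.covariate_effects) + [cand]
            fit = _fit_with_effects(data, current.model, effects, fit_kwargs)
            dofv = current.ofv - fit.ofv if fit.converged else float("nan")
            results.append((cand, fit, dofv))
            if fit.converged and np.isfinite(dofv) and dofv > threshold:
                if best is None or dofv > best[2]:
                    best = (cand, fit, dofv)
        for cand, fit, dofv in results:
            rows.append({"step": step, "candidate": cand.label, "delta_ofv": dofv,
                         "converged": fit.converged,
                         "decision": "added" if best is not None and cand is best[0] else "not added"})
        if best is None:
            break
        current = best[1]
        remaining.remove(best[0])
    trace = pd.DataFrame(rows, columns=["step", "candidate", "delta_ofv", "converged", "decision"])
    return SelectionResult(final=current, trace=trace)


def backward_eliminate(data, full, threshold: float = BACKWARD_DOFV,
                       **fit_kwargs) -> SelectionResult:
    """Backward elimination of covariate effects.

    At each step every retained effect is removed (alone) and the model
    refitted; the effect whose removal increases the OFV least is dropped if
    that increase stays below ``threshold`` (default 10.83, p < 0.001 on
    1 df).  Effects whose removal raises the OFV by at least the threshold
    are significant and retained.
    """
    if not full.converged:
        raise ValueError("backward_eliminate requires a converged full-model fit")
    fit_kwargs.setdefault("compute_se", False)
    current = full
    rows = []
    step = 0
    while current.model.covariate_effects:
        step += 1
        best = None
        results = []
        for eff in current.model.covariate_effects:
            effects = [e for e in current.model.covariate_effects if e is not eff]
            fit = _fit_with_effects(data, current.model, effects, fit_kwargs)
            dofv = fit.ofv - current.ofv if fit.converged else float("nan")
            results.append((eff, fit, dofv))
            if fit.converged and np.isfinite(dofv) and dofv < threshold:
                if best is None or dofv < best[2]:
                    best = (eff, fit, dofv)
        for eff, fit, dofv in results:
            rows.append({"step": step, "candidate": eff.label, "delta_ofv": dofv,
                         "converged": fit.converged,
                         "decision": "removed" if best is not None and eff is best[0] else "retained"})
        if best is None:
            break
        current = best[1]
    trace = pd.DataFrame(rows, columns=["step", "candidate", "delta_ofv", "converged", "decision"])
    return SelectionResult(final=current, trace=trace)
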
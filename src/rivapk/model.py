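"""Population model: fixed effects, between-subject variability, residual error.

A subject's parameters are log-normal around covariate-adjusted typical
values: ``p_i = theta * m_cov(x_i) * exp(eta_i)`` with ``eta ~ N(0, omega2)``
on the log scale.  Between-subject variability (IIV) is carried on CL/F, V/F,
D1 and ALAG1 only (the absorption rate constant has none), with a diagonal
covariance.  Residual error is the combined proportional + additive model:
``Var[y | f] = sigma2_prop * f**2 + sigma2_add``.

Reporting conventions
---------------------
IIV is reported as a coefficient of variation via the exact log-normal
transform ``CV% = 100*sqrt(exp(omega2) - 1)`` (``cv_approx=False`` in
:func:`omega2_from_cv` switches to the first-order convention CV = omega).
The stored residual components default to the usual mixed convention:
``sigma_prop`` a variance (dimensionless) and ``sigma_add`` a standard
deviation in µg/L; both are switchable per model (``prop_is_variance``,
``add_is_sd``) because published tables rarely declare the scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .covariates import CovariateEffect, covariate_multiplier
from .pkmodel import IndivParams

__all__ = [
    "THETA_NAMES",
    "ETA_NAMES",
    "PopModel",
    "omega2_from_cv",
    "cv_from_omega2",
    "individual_params",
    "residual_variance",
]

THETA_NAMES = ("ka", "cl_f", "v_f", "d1", "alag1")
#: parameters carrying between-subject variability, in eta-vector order
ETA_NAMES = ("cl_f", "v_f", "d1", "alag1")
#: index of each eta dimension within the theta vector
ETA_THETA_INDEX = (1, 2, 3, 4)


def omega2_from_cv(cv_percent, approx: bool = False):
    """Log-scale variance for a log-normal CV given in percent.

    Exact: ``omega2 = ln(1 + (CV/100)**2)``; the first-order alternative
    (``approx=True``) is ``omega2 = (CV/100)**2``.
    """
    cv = np.asarray(cv_percent, dtype=float) / 100.0
    return cv**2 if approx else np.log1p(cv**2)


def cv_from_omega2(omega2, approx: bool = False):
    """CV% implied by a log-scale variance (inverse of :func:`omega2_from_cv`)."""
    w2 = np.asarray(omega2, dtype=float)
    return 100.0 * (np.sqrt(w2) if approx else np.sqrt(np.expm1(w2)))


@dataclass(frozen=True)
class PopModel:
    """Fixed effects, IIV variances, residual error and covariate effects.

    Attributes
    ----------
    theta : array-like, shape (5,)
        Typical values in ``THETA_NAMES`` order (ka, cl_f, v_f, d1, alag1).
    omega2 : array-like, shape (4,)
        Log-scale IIV variances in ``ETA_NAMES`` order; a zero entry means
        the parameter carries no between-subject variability.
    sigma_prop, sigma_add : float
        Residual components, interpreted per ``prop_is_variance`` /
        ``add_is_sd``.
    covariate_effects : tuple of CovariateEffect
    """

    theta: tuple
    omega2: tuple = (0.0, 0.0, 0.0, 0.0)
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    prop_is_variance: bool = True
    add_is_sd: bool = True
    covariate_effects: tuple = ()

    def __post_init__(self) -> None:
        theta = tuple(float(x) for x in self.theta)
        omega2 = tuple(float(x) for x in self.omega2)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "omega2", omega2)
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))
        if len(theta) != len(THETA_NAMES):
            raise ValueError(f"theta must have {len(THETA_NAMES)} entries {THETA_NAMES}")
        if any(not np.isfinite(x) or x <= 0 for x in theta):
            raise ValueError(f"theta entries must be positive and finite, got {theta}")
        if len(omega2) != len(ETA_NAMES):
            raise ValueError(f"omega2 must have {len(ETA_NAMES)} entries {ETA_NAMES}")
        if any(x < 0 or not np.isfinite(x) for x in omega2):
            raise ValueError(f"omega2 entries must be nonnegative, got {omega2}")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual components must be nonnegative")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError("at least one residual component must be positive")
        for eff in self.covariate_effects:
            if eff.target_param not in THETA_NAMES:
                raise ValueError(f"unknown covariate target {eff.target_param!r}")

    # -- residual scale conversion --------------------------------------
    @property
    def sigma2_prop(self) -> float:
        """Proportional residual component as a variance (dimensionless)."""
        return self.sigma_prop if self.prop_is_variance else self.sigma_prop**2

    @property
    def sigma2_add(self) -> float:
        """Additive residual component as a variance ((µg/L)^2)."""
        return self.sigma_add**2 if self.add_is_sd else self.sigma_add

    # -- convenience views ----------------------------------------------
    @property
    def theta_dict(self) -> dict:
        return dict(zip(THETA_NAMES, self.theta))

    def iiv_cv_percent(self) -> dict:
        """IIV per parameter as CV% via the exact log-normal transform."""
        return {name: float(cv_from_omega2(w2)) for name, w2 in zip(ETA_NAMES, self.omega2)}

    def typical_params(self, covariates=None) -> IndivParams:
        """Covariate-adjusted typical subject (eta = 0)."""
        return individual_params(self, np.zeros(len(ETA_NAMES)), covariates)

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "theta": dict(zip(THETA_NAMES, map(float, self.theta))),
            "omega2": dict(zip(ETA_NAMES, map(float, self.omega2))),
            "sigma_prop": float(self.sigma_prop),
            "sigma_add": float(self.sigma_add),
            "prop_is_variance": self.prop_is_variance,
            "add_is_sd": self.add_is_sd,
        }
        if self.covariate_effects:
            d["covariate_effects"] = [
                {"target_param": e.target_param, "covariate": e.covariate,
                 "form": e.form, "theta_cov": e.theta_cov,
                 "cov_median": e.cov_median, "reference": e.reference}
                for e in self.covariate_effects
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopModel":
        effects = tuple(CovariateEffect(**e) for e in d.get("covariate_effects", ()))
        return cls(
            theta=tuple(d["theta"][k] for k in THETA_NAMES),
            omega2=tuple(d.get("omega2", dict.fromkeys(ETA_NAMES, 0.0)).get(k, 0.0)
                         for k in ETA_NAMES),
            sigma_prop=d.get("sigma_prop", 0.0),
            sigma_add=d.get("sigma_add", 0.0),
            prop_is_variance=d.get("prop_is_variance", True),
            add_is_sd=d.get("add_is_sd", True),
            covariate_effects=effects,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def individual_params(model: PopModel, eta, covariates=None) -> IndivParams:
    """Realise one subject's parameters from the population model.

    ``p_i = theta * m_cov(x_i) * exp(eta)`` where ``eta`` follows the
    ``ETA_NAMES`` order and ``covariates`` maps covariate name -> value
    (may be None when the model has no covariate effects).
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(ETA_NAMES),):
        raise ValueError(f"eta must have shape ({len(ETA_NAMES)},)")
    values = np.array(model.theta, dtype=float)
    for eff in model.covariate_effects:
        if covariates is None or eff.covariate not in covariates:
            raise KeyError(f"covariate {eff.covariate!r} required by the model is missing")
        idx = THETA_NAMES.index(eff.target_param)
        values[idx] *= covariate_multiplier(eff, covariates[eff.covariate])
    values[list(ETA_THETA_INDEX)] *= np.exp(eta)
    return IndivParams(*values)


def residual_variance(f, model: PopModel):
    """Residual variance of an observation with model prediction ``f`` (µg/L).

    Combined error model: ``sigma2_prop * f**2 + sigma2_add`` with the
    components converted to variances per the model's scale conventions.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("model predictions must be nonnegative")
    out = model.sigma2_prop * f**2 + model.sigma2_add
    return float(out) if out.ndim == 0 else out
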
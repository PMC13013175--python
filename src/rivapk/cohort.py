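"""Synthetic cohorts and datasets emulating a sparse-sampling PopPK study.

The generator reproduces the *design* of the study it emulates — subject
count, dose allocation, nominal sampling times with uniform jitter, an extra
mid-interval sample in a configurable subset, quantification-limit censoring
— and draws covariates from marginal distributions matched to published
summary statistics.  Continuous covariates use a log-normal matched to the
published median and truncated to the published (min, max), with the spread
set so the printed range corresponds to the central 99% of the untruncated
distribution; categorical covariates follow the printed frequencies.
Covariates are drawn independently (no joint structure is published), which
is a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .events import EventTable
from .model import ETA_NAMES, PopModel, individual_params

__all__ = [
    "CovariateSpec",
    "DesignConfig",
    "SimulatedDataset",
    "generate_cohort",
    "generate_dataset",
]

#: z-quantile mapping the printed (min, max) to a central 99% interval
_RANGE_Z = 2.5758293035489004


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate.

    ``kind="lognormal"``: median/minimum/maximum describe a truncated
    log-normal.  ``kind="categorical"``: ``levels`` and ``probs`` give the
    level frequencies.
    """

    name: str
    kind: str  # "lognormal" | "categorical"
    median: float | None = None
    minimum: float | None = None
    maximum: float | None = None
    levels: tuple = ()
    probs: tuple = ()
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind == "lognormal":
            if not (0 < self.minimum <= self.median <= self.maximum):
                raise ValueError(
                    f"covariate {self.name!r}: need 0 < min <= median <= max, "
                    f"got ({self.minimum}, {self.median}, {self.maximum})"
                )
        elif self.kind == "categorical":
            if len(self.levels) != len(self.probs) or not self.levels:
                raise ValueError(f"covariate {self.name!r}: levels/probs mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-6:
                raise ValueError(f"covariate {self.name!r}: probabilities must sum to 1")
        else:
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    def draw(self, n: int, rng: np.random.Generator):
        if self.kind == "categorical":
            return rng.choice(np.asarray(self.levels, dtype=object), size=n, p=self.probs)
        mu = np.log(self.median)
        sigma = max((np.log(self.maximum) - np.log(self.minimum)) / (2.0 * _RANGE_Z), 1e-6)
        out = np.empty(n)
        filled = 0
        while filled < n:  # rejection sampling within the printed range
            draw = np.exp(rng.normal(mu, sigma, size=2 * (n - filled)))
            keep = draw[(draw >= self.minimum) & (draw <= self.maximum)][: n - filled]
            out[filled: filled + len(keep)] = keep
            filled += len(keep)
        return out


@dataclass(frozen=True)
class DesignConfig:
    """Study-design settings for cohort and dataset generation."""

    n_subjects: int = 38
    doses: tuple = (5.0, 10.0)  # mg, once daily
    dose_probs: tuple = (30 / 38, 8 / 38)
    sample_times: tuple = (2.0, 4.0, 24.0)  # h after the observed dose
    extra_sample_time: float = 8.0
    n_extra: int = 23  # subjects receiving the extra sample
    jitter: float = 0.5  # uniform half-width on sampling times, h
    lloq: float = 1.0  # µg/L
    dose_interval: float = 24.0
    n_doses: int = 1  # single observed dose for the estimation design
    covariates: tuple = ()  # CovariateSpec entries
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.doses) != len(self.dose_probs):
            raise ValueError("doses and dose_probs must have equal length")
        if abs(sum(self.dose_probs) - 1.0) > 1e-6:
            raise ValueError("dose allocation probabilities must sum to 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.lloq <= 0:
            raise ValueError("LLOQ must be > 0")
        if not 0 <= self.n_extra <= self.n_subjects:
            raise ValueError("n_extra must lie in [0, n_subjects]")

    def sample_times_full(self) -> tuple:
        """All nominal sampling times, including the extra mid-interval one."""
        times = set(self.sample_times)
        if self.n_extra > 0:
            times.add(self.extra_sample_time)
        return tuple(sorted(times))

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in
             ("n_subjects", "doses", "dose_probs", "sample_times", "extra_sample_time",
              "n_extra", "jitter", "lloq", "dose_interval", "n_doses", "seed")}
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        d["covariates"] = [
            {f: getattr(c, f) for f in
             ("name", "kind", "median", "minimum", "maximum", "levels", "probs", "unit")}
            for c in self.covariates
        ]
        for c in d["covariates"]:
            c["levels"], c["probs"] = list(c["levels"]), list(c["probs"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        covs = tuple(
            CovariateSpec(**{**c, "levels": tuple(c.get("levels", ())),
                             "probs": tuple(c.get("probs", ()))})
            for c in d.pop("covariates", [])
        )
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(covariates=covs, **d)


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated dataset plus the ground truth that produced it."""

    table: EventTable
    truth: pd.DataFrame  # per subject: eta_*, realised parameters
    n_blq: int  # observations censored below the LLOQ (dropped by default)


def _allocate_doses(cfg: DesignConfig, rng: np.random.Generator) -> np.ndarray:
    """Dose per subject: largest-remainder counts from the allocation
    probabilities, randomly permuted (so n=38 at 30:8 odds yields exactly
    30 and 8 subjects)."""
    exact = np.array(cfg.dose_probs) * cfg.n_subjects
    counts = np.floor(exact).astype(int)
    for _ in range(cfg.n_subjects - counts.sum()):
        counts[np.argmax(exact - counts)] += 1
    doses = np.repeat(cfg.doses, counts).astype(float)
    return rng.permutation(doses)


def generate_cohort(cfg: DesignConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a virtual cohort: one row per subject with covariates and DOSE."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    data = {"ID": np.arange(1, cfg.n_subjects + 1)}
    data["DOSE"] = _allocate_doses(cfg, rng)
    for spec in cfg.covariates:
        data[spec.name] = spec.draw(cfg.n_subjects, rng)
    return pd.DataFrame(data)


def generate_dataset(cohort: pd.DataFrame, model: PopModel, cfg: DesignConfig,
                     seed: int | None = None, keep_blq: bool = False) -> SimulatedDataset:
    """Simulate an event table for ``cohort`` under ``model`` and ``cfg``.

    Each subject receives ``cfg.n_doses`` doses of their assigned amount,
    ``cfg.dose_interval`` apart, starting at time 0; samples are drawn at the
    nominal times (plus the extra mid-interval sample in ``cfg.n_extra``
    randomly chosen subjects), jittered uniformly by ±``cfg.jitter`` h after
    the last dose.  Observations get combined proportional+additive residual
    error; values below the LLOQ are flagged and, by default, dropped with
    their count reported.  The per-subject random effects and realised
    parameters are returned alongside for recovery experiments.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sd = np.sqrt(np.asarray(model.omega2))
    extra_ids = set(rng.choice(cohort["ID"].to_numpy(), size=cfg.n_extra, replace=False))
    cov_cols = [c for c in cohort.columns if c not in ("ID", "DOSE")]

    rows, truth_rows = [], []
    n_blq = 0
    last_dose_time = (cfg.n_doses - 1) * cfg.dose_interval
    for _, subj in cohort.iterrows():
        sid = int(subj["ID"])
        dose = float(subj["DOSE"])
        covs = {c: subj[c] for c in cov_cols}
        eta = rng.normal(0.0, 1.0, size=len(ETA_NAMES)) * sd
        params = individual_params(model, eta, covs)

        nominal = list(cfg.sample_times)
        if sid in extra_ids:
            nominal.append(cfg.extra_sample_time)
        nominal = np.sort(np.asarray(nominal, dtype=float))
        times = last_dose_time + nominal + rng.uniform(-cfg.jitter, cfg.jitter, size=len(nominal))
        times = np.sort(np.maximum(times, 0.0))

        for k in range(cfg.n_doses):
            rows.append({"ID": sid, "TIME": k * cfg.dose_interval, "AMT": dose,
                         "EVID": 1, "DV": np.nan, "MDV": 1, "BLQ": 0, **covs})
        from .pkmodel import _conc_kernel  # single-dose kernel, superposed below

        f = np.zeros(len(times))
        for k in range(cfg.n_doses):
            f += _conc_kernel(times - k * cfg.dose_interval, dose,
                              params.ka, params.cl_f, params.v_f, params.d1, params.alag1)
        v = model.sigma2_prop * f**2 + model.sigma2_add
        y = f + np.sqrt(v) * rng.standard_normal(len(times))
        for t, yv in zip(times, y):
            blq = yv < cfg.lloq
            if blq:
                n_blq += 1
                if not keep_blq:
                    continue
            rows.append({"ID": sid, "TIME": float(t),
                         "AMT": np.nan, "EVID": 0,
                         "DV": np.nan if blq else float(yv),
                         "MDV": 1 if blq else 0, "BLQ": int(blq), **covs})

        truth_rows.append({"ID": sid, "DOSE": dose,
                           **{f"eta_{n}": e for n, e in zip(ETA_NAMES, eta)},
                           "ka": params.ka, "cl_f": params.cl_f, "v_f": params.v_f,
                           "d1": params.d1, "alag1": params.alag1})

    df = pd.DataFrame(rows)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable",
                        ascending=[True, True, False]).reset_index(drop=True)
    return SimulatedDataset(table=EventTable(df), truth=pd.DataFrame(truth_rows), n_blq=n_blq)
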
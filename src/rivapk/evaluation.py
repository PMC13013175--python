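"""Model qualification: goodness-of-fit tables, prediction-corrected visual
predictive checks, and the case-resampling bootstrap.

The pcVPC simulates replicate datasets at the original design, normalises
each observed and simulated value by the ratio of its bin-median population
prediction to its own population prediction (the standard prediction
correction), and compares observed percentiles per time bin with the 90%
confidence band of the corresponding simulated percentiles.  The bootstrap
resamples whole subjects with replacement, refits every replicate, and
summarises converged replicates by medians and 95% nonparametric percentile
intervals; a replicate counts as converged when the optimiser reaches an OFV
minimum, whether or not a covariance step would have succeeded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventTable
from .foce import FitResult, FoceEngine, fit_foce
from .model import ETA_NAMES, PopModel

__all__ = ["VPCResult", "BootstrapResult", "pcvpc", "bootstrap", "gof_table",
           "simulate_dv"]

log = logging.getLogger(__name__)


@dataclass
class VPCResult:
    """Binned pcVPC summary.

    ``table`` has one row per (bin, percentile) with the prediction-corrected
    observed percentile and the simulated 90% confidence band.
    """

    table: pd.DataFrame
    percentiles: tuple
    n_sim: int

    @property
    def coverage(self) -> float:
        """Fraction of (bin x percentile) cells whose observed percentile
        falls inside the simulated 90% band."""
        t = self.table
        inside = (t["observed"] >= t["band_lo"]) & (t["observed"] <= t["band_hi"])
        return float(inside.mean())


@dataclass
class BootstrapResult:
    """Case-resampling bootstrap of the population-model parameters."""

    estimates: pd.DataFrame  # one row per converged replicate
    summary: pd.DataFrame  # parameter, median, pi_lo, pi_hi
    convergence_fraction: float
    replicate_ids: list  # the resampled subject-id tuples, for reproducibility


def simulate_dv(engine: FoceEngine, model: PopModel, rng: np.random.Generator) -> np.ndarray:
    """One simulated observation vector at the dataset's design: draw etas
    from the IIV distribution and add combined residual error."""
    sd = np.sqrt(np.asarray(model.omega2))
    etas = rng.standard_normal((engine.n_subj, len(ETA_NAMES))) * sd[None, :]
    f = engine.predict(etas)
    v = model.sigma2_prop * f**2 + model.sigma2_add
    return f + np.sqrt(v) * rng.standard_normal(engine.n_obs)


def _assign_bins(times: np.ndarray, nominal: np.ndarray) -> np.ndarray:
    """Nearest nominal sampling time per observation."""
    return nominal[np.argmin(np.abs(times[:, None] - nominal[None, :]), axis=1)]


def pcvpc(data: EventTable, fit: FitResult, n_sim: int = 1000, seed=None,
          nominal_times=(2.0, 4.0, 8.0, 24.0), percentiles=(5.0, 50.0, 95.0),
          band: float = 90.0, min_bin: int = 3) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observations are binned by nearest nominal sampling time (the study's
    actual times jitter around the nominal grid); bins with fewer than
    ``min_bin`` observations are merged into their nearest neighbour (logged).
    ``n_sim`` replicate datasets are simulated at the original design from
    the fitted model, and each observed/simulated value is scaled by
    (bin-median population prediction) / (own population prediction) before
    percentile comparison.
    """
    if not fit.converged:
        raise ValueError("pcvpc requires a converged fit")
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2 to form percentile confidence bands")
    rng = np.random.default_rng(seed)
    engine = FoceEngine(data, fit.model)
    y = engine.y
    times = engine.t_obs
    pred = engine.predict(np.zeros((engine.n_subj, len(ETA_NAMES))))

    bins = _assign_bins(times, np.asarray(nominal_times, float))
    # merge undersized bins into their nearest neighbour
    while True:
        uniq, counts = np.unique(bins, return_counts=True)
        small = uniq[counts < min_bin]
        if small.size == 0 or uniq.size == 1:
            break
        b = small[0]
        others = uniq[uniq != b]
        target = others[np.argmin(np.abs(others - b))]
        log.info("pcVPC: merging bin %.3g h (%d obs) into %.3g h", b,
                 counts[uniq == b][0], target)
        bins[bins == b] = target

    uniq = np.unique(bins)
    correction = np.empty_like(pred)
    for b in uniq:
        sel = bins == b
        correction[sel] = np.median(pred[sel]) / np.maximum(pred[sel], 1e-12)
    y_pc = y * correction

    sims = np.empty((n_sim, engine.n_obs))
    for s in range(n_sim):
        sims[s] = simulate_dv(engine, fit.model, rng) * correction

    lo_q, hi_q = (100.0 - band) / 2.0, 100.0 - (100.0 - band) / 2.0
    rows = []
    for b in uniq:
        sel = bins == b
        for p in percentiles:
            obs_p = float(np.percentile(y_pc[sel], p))
            sim_p = np.percentile(sims[:, sel], p, axis=1)
            rows.append({"bin": float(b), "n_obs": int(sel.sum()), "percentile": p,
                         "observed": obs_p,
                         "band_lo": float(np.percentile(sim_p, lo_q)),
                         "band_hi": float(np.percentile(sim_p, hi_q)),
                         "sim_median": float(np.median(sim_p))})
    return VPCResult(table=pd.DataFrame(rows), percentiles=tuple(percentiles),
                     n_sim=n_sim)


def bootstrap(data: EventTable, init: PopModel, n_reps: int = 1000, seed=None,
              **fit_kwargs) -> BootstrapResult:
    """Nonparametric case-resampling bootstrap.

    Subjects are resampled with replacement to the original subject count
    (unstratified); every replicate is refitted from ``init``.  Replicates
    that fail to reach a minimum are retained in the convergence bookkeeping
    but excluded from the percentile summaries.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fit_kwargs.setdefault("compute_se", False)
    rng = np.random.default_rng(seed)
    ids = data.subject_ids
    replicate_ids = []
    records = []
    n_conv = 0
    for rep in range(n_reps):
        chosen = tuple(rng.choice(ids, size=len(ids), replace=True))
        replicate_ids.append(chosen)
        sample = data.subset(chosen, renumber=True)
        try:
            fit = fit_foce(sample, init, **fit_kwargs)
        except Exception as exc:  # a degenerate resample is data, not an error
            warnings.warn(f"bootstrap replicate {rep} failed: {exc}")
            continue
        if fit.converged:
            n_conv += 1
            records.append({"replicate": rep, **fit.estimates})
    estimates = pd.DataFrame(records)
    rows = []
    for name in estimates.columns.drop("replicate", errors="ignore"):
        vals = estimates[name].to_numpy(float)
        rows.append({"parameter": name, "median": float(np.median(vals)),
                     "pi_lo": float(np.percentile(vals, 2.5)),
                     "pi_hi": float(np.percentile(vals, 97.5))})
    return BootstrapResult(estimates=estimates, summary=pd.DataFrame(rows),
                           convergence_fraction=n_conv / n_reps,
                           replicate_ids=replicate_ids)


def gof_table(fit: FitResult, data: EventTable) -> pd.DataFrame:
    """Tidy goodness-of-fit table: one row per usable observation with the
    population prediction (eta = 0), individual prediction (empirical Bayes
    etas) and conditional weighted residual."""
    from .foce import cwres as _cwres

    if not fit.converged:
        raise ValueError("gof_table requires a converged fit")
    engine = FoceEngine(data, fit.model)
    pred = engine.predict(np.zeros((engine.n_subj, len(ETA_NAMES))))
    etas = np.zeros((engine.n_subj, len(ETA_NAMES)))
    for k, sid in enumerate(engine.subject_ids):
        if sid in fit.etas.index:
            etas[k] = fit.etas.loc[sid].to_numpy()
    ipred = engine.predict(etas)
    res = _cwres(fit, data)
    obs = data.observations
    return pd.DataFrame({"ID": obs["ID"].to_numpy(), "TIME": obs["TIME"].to_numpy(),
                         "DV": obs["DV"].to_numpy(), "PRED": pred, "IPRED": ipred,
                         "CWRES": res["CWRES"].to_numpy()})
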
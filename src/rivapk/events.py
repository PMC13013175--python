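"""NONMEM-convention event tables: one row per dose or observation.

Canonical columns: ``ID`` (subject), ``TIME`` (h), ``AMT`` (dose mg, missing
on observation rows), ``EVID`` (1 dose / 0 observation), ``DV`` (observed
concentration µg/L, missing on dose rows), ``MDV`` (1 when DV missing or
excluded), ``BLQ`` (1 when the value fell below the quantification limit).
Any further columns are carried as covariates, assumed constant within a
subject.  Missing values are written as ``"."`` in CSV, per the usual
dataset convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EventTable", "read_event_table", "write_event_table"]

MANDATORY = ("ID", "TIME", "AMT", "EVID", "DV")
CANONICAL = ("ID", "TIME", "AMT", "EVID", "DV", "MDV", "BLQ")


@dataclass(frozen=True)
class EventTable:
    """Validated long-format dose/observation records for one cohort."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", _validate(self.df))

    # -- views ------------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        """Subject ids in order of first appearance."""
        return self.df["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def observations(self) -> pd.DataFrame:
        """Usable observation rows (EVID 0, MDV 0)."""
        return self.df[(self.df["EVID"] == 0) & (self.df["MDV"] == 0)]

    @property
    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def covariate_columns(self) -> list:
        return [c for c in self.df.columns if c not in CANONICAL]

    def covariates(self) -> pd.DataFrame:
        """One row per subject (first record), indexed by ID."""
        return self.df.groupby("ID", sort=False)[self.covariate_columns].first()

    def subset(self, ids, renumber: bool = False) -> "EventTable":
        """Rows of the listed subjects, in the listed order (with repeats).

        ``renumber=True`` assigns fresh sequential ids 1..n, which makes
        bootstrap resamples (where one subject may appear several times)
        well-formed tables.
        """
        parts = []
        for new_id, sid in enumerate(ids, start=1):
            part = self.df[self.df["ID"] == sid].copy()
            if renumber:
                part["ID"] = new_id
            parts.append(part)
        return EventTable(pd.concat(parts, ignore_index=True))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"event table lacks mandatory columns: {missing}")
    df["ID"] = df["ID"].astype(int)
    for col in ("TIME", "AMT", "DV"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["EVID"] = df["EVID"].astype(int)
    if "MDV" not in df.columns:
        df["MDV"] = np.where(df["DV"].notna(), 0, 1)
    df["MDV"] = df["MDV"].astype(int)
    if "BLQ" not in df.columns:
        df["BLQ"] = 0
    df["BLQ"] = df["BLQ"].astype(int)

    bad = df.index[df["TIME"] < 0].tolist()
    if bad:
        raise ValueError(f"negative TIME in rows {bad}")
    bad = df.index[(df["EVID"] == 1) & (df["AMT"].isna() | (df["AMT"] < 0))].tolist()
    if bad:
        raise ValueError(f"dose rows with missing or negative AMT: rows {bad}")
    bad = df.index[(df["EVID"] == 1) & df["DV"].notna()].tolist()
    if bad:
        raise ValueError(f"dose rows must not carry an observation: rows {bad}")
    bad = df.index[(df["EVID"] == 0) & (df["MDV"] == 0) & df["DV"].isna()].tolist()
    if bad:
        raise ValueError(f"observation rows with MDV 0 but missing DV: rows {bad}")

    for sid, sub in df.groupby("ID", sort=False):
        t = sub["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            row = sub.index[np.argmin(np.diff(t) >= 0) + 1]
            raise ValueError(f"times of subject {sid} not sorted (row {row})")
        obs = sub[(sub["EVID"] == 0)]
        dose_t = sub.loc[sub["EVID"] == 1, "TIME"]
        if len(obs) and (dose_t.empty or obs["TIME"].iloc[0] < dose_t.iloc[0]):
            warnings.warn(
                f"subject {sid} has an observation before any dose (pre-dose sample)",
                stacklevel=3,
            )

    # canonical column order: mandatory block, then covariates
    cov_cols = [c for c in df.columns if c not in CANONICAL]
    return df[[*CANONICAL, *cov_cols]].reset_index(drop=True)


def write_event_table(table: EventTable, path) -> None:
    """Write the canonical CSV (missing values as ``"."``)."""
    table.df.to_csv(path, index=False, na_rep=".")


def read_event_table(path) -> EventTable:
    """Read and validate a canonical CSV event table."""
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     float_precision="round_trip")
    return EventTable(df)
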
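"""Data model, CSV I/O, cohort filters and case labelling.

The universal input is a tidy long-format table: one row per cow-visit with
the cow identifier, parity class, day relative to parturition (negative =
ante partum, 0 = parturition) and the serum biomarker panel — BHB and NEFA in
mmol/L, total bilirubin in µmol/L and AST in U/L.  A cow is *hyperketonemic*
if any of her BHB samples strictly exceeds 0.8 mmol/L, and a *subclinical
ketosis* (SCK) case above 1.2 mmol/L; cows at or below the threshold form the
respective control group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BIOMARKERS",
    "BHB_HYPERKETONEMIA",
    "BHB_SCK",
    "DAY_RANGE",
    "ObservationTable",
    "CaseLabels",
    "read_observations",
    "write_observations",
    "filter_min_observations",
    "label_cows",
    "assess_normality",
    "NormalityReport",
]

#: Serum biomarker columns, in panel order.
BIOMARKERS: tuple[str, ...] = ("bhb", "nefa", "tbil", "ast")

#: Case-definition thresholds (mmol/L BHB, strict ">").
BHB_HYPERKETONEMIA: float = 0.8
BHB_SCK: float = 1.2

#: Admissible days relative to parturition.
DAY_RANGE: tuple[int, int] = (-60, 120)

REQUIRED_COLUMNS: tuple[str, ...] = ("cow_id", "parity", "day", *BIOMARKERS)
PARITY_CLASSES: tuple[str, str] = ("primiparous", "multiparous")


class ObservationTable:
    """Validated long-format cow-visit table.

    Wraps a :class:`pandas.DataFrame` sorted by ``(cow_id, day)`` with no
    duplicate cow/day pairs and strictly positive biomarker values (so the
    log transform is always defined); missing biomarker values are NaN.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        if "post_treatment" not in df.columns:
            df["post_treatment"] = False
        df["cow_id"] = df["cow_id"].astype(str)
        df["day"] = df["day"].astype(int)
        df["post_treatment"] = df["post_treatment"].astype(bool)
        for b in BIOMARKERS:
            df[b] = pd.to_numeric(df[b], errors="raise").astype(float)

        bad_day = df[(df["day"] < DAY_RANGE[0]) | (df["day"] > DAY_RANGE[1])]
        if len(bad_day):
            raise ValueError(
                f"{len(bad_day)} row(s) with day outside {DAY_RANGE}: "
                f"days {sorted(bad_day['day'].unique())[:10]}"
            )
        nonpos = df[list(BIOMARKERS)].le(0.0)
        if nonpos.any().any():
            rows = df.index[nonpos.any(axis=1)].tolist()[:10]
            raise ValueError(
                f"non-positive biomarker value(s) at row(s) {rows}; "
                "all concentrations must be > 0 (log scale must be defined)"
            )
        bad_par = set(df["parity"]) - set(PARITY_CLASSES)
        if bad_par:
            raise ValueError(f"unknown parity class(es): {sorted(bad_par)}")

        dup = df.duplicated(subset=["cow_id", "day"], keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, ["cow_id", "day"]].drop_duplicates().itertuples(index=False)
            )
            listing = ", ".join(f"({o.cow_id}, day {o.day})" for o in offenders)
            raise ValueError(f"duplicate (cow_id, day) pairs: {listing}")

        self.df = df.sort_values(["cow_id", "day"], kind="stable").reset_index(drop=True)

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservationTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def n_cows(self) -> int:
        return self.df["cow_id"].nunique()

    @property
    def cow_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["cow_id"]))

    def cow(self, cow_id: str) -> pd.DataFrame:
        """All visits of one cow, sorted by day."""
        return self.df[self.df["cow_id"] == str(cow_id)]

    def groupby_cow(self):
        return self.df.groupby("cow_id", sort=True)

    def drop_post_treatment(self) -> "ObservationTable":
        """Table without samples drawn after a supplementation week."""
        return ObservationTable(self.df[~self.df["post_treatment"]])


def read_observations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[ObservationTable, list[str]]:
    """Read a cow-visit CSV.

    Parameters
    ----------
    path
        CSV with a header row.  Canonical columns:
        ``cow_id,parity,day,bhb,nefa,tbil,ast,post_treatment``.
    dialect
        Optional mapping from canonical column name to the name used in the
        file (e.g. ``{"bhb": "BHBA_mmol_l"}``).

    Returns
    -------
    (table, rejected)
        The validated table plus a per-row report of rejected rows (rows with
        unparseable numeric fields are dropped, not fatal).

    Raises
    ------
    ValueError
        If a required column is missing, or duplicate ``(cow_id, day)`` pairs
        remain after parsing.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    rejected: list[str] = []
    keep = np.ones(len(raw), dtype=bool)
    day = pd.to_numeric(raw["day"], errors="coerce")
    bad = day.isna() | (day != day.round())
    for i in raw.index[bad]:
        rejected.append(f"row {i + 2}: unparseable integer day {raw.at[i, 'day']!r}")
    keep &= ~bad.to_numpy()
    for b in BIOMARKERS:
        vals = pd.to_numeric(raw[b], errors="coerce")
        # empty field = missing biomarker, allowed; non-numeric junk is not
        junk = vals.isna() & raw[b].notna() & (raw[b].str.strip() != "")
        for i in raw.index[junk]:
            rejected.append(f"row {i + 2}: unparseable {b} value {raw.at[i, b]!r}")
        keep &= ~junk.to_numpy()
        raw[b] = vals
    raw["day"] = day
    if "post_treatment" in raw.columns:
        raw["post_treatment"] = (
            raw["post_treatment"].str.strip().str.lower().isin(("1", "true", "yes"))
        )
    table = ObservationTable(raw[keep])
    return table, rejected


def write_observations(table: ObservationTable, path: str | Path) -> None:
    """Write a table to CSV in the canonical column layout (UTF-8, header)."""
    out = table.df[[*REQUIRED_COLUMNS, "post_treatment"]].copy()
    out["post_treatment"] = out["post_treatment"].astype(int)
    out.to_csv(path, index=False)


def filter_min_observations(table: ObservationTable, min_obs: int = 11) -> ObservationTable:
    """Keep only cows with at least ``min_obs`` visits.

    The study cohort retained cows with more than 10 observations, i.e. the
    default ``min_obs=11`` (>= 11 visits).  Visit rows of retained cows are
    untouched; an empty result is allowed.
    """
    if min_obs < 1:
        raise ValueError(f"min_obs must be >= 1, got {min_obs}")
    counts = table.df.groupby("cow_id")["day"].size()
    keep = counts.index[counts >= min_obs]
    return ObservationTable(table.df[table.df["cow_id"].isin(keep)])


@dataclass(frozen=True)
class CaseLabels:
    """Per-cow case status at one BHB threshold.

    A cow is a case iff *any* of her BHB samples strictly exceeds
    ``threshold``; ``onset_day`` is the day of the first exceedance and is
    present exactly for cases.
    """

    threshold: float
    is_case: dict[str, bool]
    onset_day: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, case in self.is_case.items():
            if case != (cid in self.onset_day):
                raise ValueError(f"onset_day present iff case violated for cow {cid}")

    @property
    def cases(self) -> list[str]:
        return [c for c, v in self.is_case.items() if v]

    @property
    def controls(self) -> list[str]:
        return [c for c, v in self.is_case.items() if not v]

    @property
    def n_cases(self) -> int:
        return sum(self.is_case.values())

    def as_series(self) -> pd.Series:
        return pd.Series(self.is_case, name="is_case")


def label_cows(table: ObservationTable, threshold: float = BHB_HYPERKETONEMIA) -> CaseLabels:
    """Label cows as case/control by strict BHB threshold exceedance.

    ``threshold=0.8`` mmol/L defines hyperketonemia, ``1.2`` mmol/L defines
    subclinical ketosis; a value of exactly ``threshold`` is a control sample
    (strict ">").  Cows whose BHB is entirely missing are excluded with a
    warning.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    is_case: dict[str, bool] = {}
    onset: dict[str, int] = {}
    for cow_id, g in table.groupby_cow():
        bhb = g["bhb"]
        if bhb.isna().all():
            warnings.warn(f"cow {cow_id} has no BHB observations; excluded from labels")
            continue
        exceed = g[bhb > threshold]
        case = len(exceed) > 0
        is_case[cow_id] = case
        if case:
            onset[cow_id] = int(exceed["day"].iloc[0])
    return CaseLabels(threshold=float(threshold), is_case=is_case, onset_day=onset)


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro–Wilk diagnostics on raw and natural-log scale."""

    w_raw: float
    p_raw: float
    w_log: float
    p_log: float
    recommendation: str  # "log" or "raw"


def assess_normality(values: Iterable[float]) -> NormalityReport:
    """Shapiro–Wilk test on raw and natural-log values.

    The recommendation is ``"log"`` when the log scale is closer to
    normality (larger Shapiro–Wilk p), mirroring the transform screening
    applied to each biomarker before model fitting.

    Raises
    ------
    ValueError
        Fewer than 3 finite values, a non-positive value (log undefined),
        or a constant vector (test degenerate).
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError(f"need >= 3 finite values, got {len(x)}")
    if np.any(x <= 0):
        raise ValueError("non-positive value encountered; log transform undefined")
    if np.ptp(x) == 0:
        raise ValueError("constant vector; normality test degenerate")
    w_raw, p_raw = stats.shapiro(x)
    w_log, p_log = stats.shapiro(np.log(x))
    return NormalityReport(
        w_raw=float(w_raw),
        p_raw=float(p_raw),
        w_log=float(w_log),
        p_log=float(p_log),
        recommendation="log" if p_log > p_raw else "raw",
    )
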
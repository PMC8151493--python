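"""Onset ECDFs, incidence proportions and the pre-partum sampling-gap statistic.

Onset of a case is the sample day of the first BHB threshold exceedance (no
interpolation between visits, matching a weekly surveillance reading).  The
onset ECDF is taken over *eventual cases only*: ``F(d)`` is the fraction of
cases whose onset lies at or before day ``d``, so ``1 - F(d)`` is the share
of future cases a single measurement on day ``d`` would miss.

The maximum over cows of the span between the last ante-partum sample and
parturition bounds from below the time grid a classification scheme can use:
an interval at least that wide guarantees every cow contributes at least one
pre-partum measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import CaseLabels, ObservationTable, label_cows

__all__ = [
    "OnsetEcdf",
    "onset_ecdf",
    "incidence_proportion",
    "max_prepartum_gap",
    "undetected_fraction",
]


@dataclass(frozen=True)
class OnsetEcdf:
    """Empirical CDF of case-onset days relative to parturition."""

    onset_days: tuple[int, ...]  # sorted, one per eventual case

    def __post_init__(self) -> None:
        object.__setattr__(self, "onset_days", tuple(sorted(self.onset_days)))

    @property
    def n_cases(self) -> int:
        return len(self.onset_days)

    def __call__(self, day: float) -> float:
        """F(day) = fraction of eventual cases with onset <= day."""
        if not self.onset_days:
            return float("nan")
        return float(np.searchsorted(self.onset_days, day, side="right")) / self.n_cases

    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique jump days and F evaluated there (for plotting/export)."""
        days = np.unique(self.onset_days)
        return days, np.array([self(d) for d in days])


def onset_ecdf(table: ObservationTable, threshold: float) -> OnsetEcdf:
    """ECDF of first-exceedance days at the given BHB threshold."""
    labels = label_cows(table, threshold)
    if not labels.onset_day:
        warnings.warn(f"no cases at BHB threshold {threshold}; ECDF is empty")
    return OnsetEcdf(onset_days=tuple(labels.onset_day.values()))


def incidence_proportion(labels: CaseLabels, n_total: int | None = None) -> float:
    """Cases divided by the total number of cows tested."""
    if n_total is None:
        n_total = len(labels.is_case)
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    return labels.n_cases / n_total


def max_prepartum_gap(table: ObservationTable) -> int:
    """Maximum over cows of days from last ante-partum sample to parturition.

    Day 0 is parturition itself, not ante partum, so only strictly negative
    days count; cows with no ante-partum sample are flagged and skipped.
    """
    gaps = []
    skipped = []
    for cow_id, g in table.groupby_cow():
        ap = g[g["day"] < 0]
        if ap.empty:
            skipped.append(cow_id)
            continue
        gaps.append(-int(ap["day"].max()))
    if skipped:
        warnings.warn(
            f"{len(skipped)} cow(s) without an ante-partum sample skipped: "
            f"{skipped[:5]}"
        )
    if not gaps:
        raise ValueError("no cow has an ante-partum sample; gap undefined")
    return max(gaps)


def undetected_fraction(ecdf: OnsetEcdf, day: int) -> float:
    """Share of eventual cases not yet past onset by ``day``: 1 - F(day)."""
    if ecdf.n_cases == 0:
        raise ValueError("empty ECDF; undetected fraction undefined")
    return 1.0 - ecdf(day)
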
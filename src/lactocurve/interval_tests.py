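"""Per-interval descriptive tests of group differences.

The study window from 15 d ante partum to 62 d post partum is tiled into
6-day intervals (13 of them).  Within each interval, every cow's log-scale
observations are first averaged — one value per cow, so repeated visits
inside an interval cannot pseudo-replicate — and the case and control groups
are then compared.

The primary comparison is a Welch two-sample t-test on the per-cow interval
means.  A literal one-sample variant (case-cow means tested against the
control mean treated as a fixed constant) is available behind a flag; the
two variants answer slightly different questions and the one-sample form is
anti-conservative because it ignores control-group sampling error.

Two extra single-day tests are run at parturition (t0) and at day 10 post
partum (t1), using nearest-neighbour linear interpolation for cows not
sampled exactly on those days.  P-values are reported uncorrected, as befits
a descriptive screen; Benjamini–Hochberg adjustment is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CaseLabels, ObservationTable

__all__ = ["IntervalTestResult", "interval_group_tests", "make_intervals"]

DEFAULT_RANGE: tuple[int, int] = (-15, 62)
DEFAULT_WIDTH: int = 6
T1_DAY: int = 10


@dataclass(frozen=True)
class IntervalTestResult:
    """Two-group comparison of per-cow mean log values in one interval."""

    label: str                     # e.g. "[-15,-9)" or "t0", "t1"
    start: float
    end: float                     # half-open [start, end); start==end for t0/t1
    biomarker: str
    mean_case: float               # log scale
    mean_control: float
    t: float
    p: float
    n_case: int
    n_control: int
    skipped: bool = False          # too few cows in a group
    p_adjusted: float | None = None


def make_intervals(
    day_range: tuple[int, int] = DEFAULT_RANGE, width: int = DEFAULT_WIDTH
) -> list[tuple[int, int]]:
    """Half-open 6-day tiles covering the inclusive day range.

    ``[-15, 62]`` spans 78 days, hence 13 tiles ``[-15,-9), [-9,-3), ...``.
    """
    lo, hi = day_range
    span = hi - lo + 1
    n = -(-span // width)  # ceil
    return [(lo + k * width, lo + (k + 1) * width) for k in range(n)]


def _per_cow_interval_means(
    table: ObservationTable, biomarker: str, start: int, end: int
) -> pd.Series:
    df = table.df
    m = (df["day"] >= start) & (df["day"] < end) & df[biomarker].notna()
    sub = df[m]
    return np.log(sub.groupby("cow_id")[biomarker].mean())


def _interpolated_values(
    table: ObservationTable, biomarker: str, day: int
) -> pd.Series:
    from .classifiers import interpolate_at

    vals = {}
    for cow_id, g in table.groupby_cow():
        gg = g[g[biomarker].notna()]
        v = interpolate_at(
            gg["day"].to_numpy(dtype=float), gg[biomarker].to_numpy(dtype=float), day
        )
        if v is not None:
            vals[cow_id] = np.log(v)
    return pd.Series(vals, dtype=float)


def _welch(case_vals: np.ndarray, ctrl_vals: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(case_vals, ctrl_vals, equal_var=False)
    return float(t), float(p)


def _one_sample(case_vals: np.ndarray, ctrl_mean: float) -> tuple[float, float]:
    t, p = stats.ttest_1samp(case_vals, ctrl_mean)
    return float(t), float(p)


def interval_group_tests(
    table: ObservationTable,
    labels: CaseLabels,
    biomarker: str,
    width: int = DEFAULT_WIDTH,
    day_range: tuple[int, int] = DEFAULT_RANGE,
    variant: str = "welch",
    adjust: bool = False,
) -> list[IntervalTestResult]:
    """Case-vs-control tests per 6-day interval plus t0 and t1 single days.

    Parameters
    ----------
    variant
        ``"welch"`` (two-sample, primary) or ``"one-sample"`` (case means
        against the control mean as a fixed constant).
    adjust
        When true, add Benjamini–Hochberg adjusted p-values across the
        non-skipped tests.

    An interval with fewer than 2 cows in either group is flagged and
    skipped; if a group is empty over the entire range, that is fatal.
    """
    if variant not in ("welch", "one-sample"):
        raise ValueError(f"unknown variant {variant!r}")
    case_ids = set(labels.cases)
    ctrl_ids = set(labels.controls)
    for name, ids in (("case", case_ids), ("control", ctrl_ids)):
        present = table.df["cow_id"].isin(ids) & (
            (table.df["day"] >= day_range[0]) & (table.df["day"] <= day_range[1])
        )
        if not present.any():
            raise ValueError(f"{name} group has no observations in {day_range}")

    jobs: list[tuple[str, float, float, pd.Series]] = []
    for start, end in make_intervals(day_range, width):
        means = _per_cow_interval_means(table, biomarker, start, end)
        jobs.append((f"[{start},{end})", start, end, means))
    for label, day in (("t0", 0), ("t1", T1_DAY)):
        vals = _interpolated_values(table, biomarker, day)
        jobs.append((label, day, day, vals))

    results: list[IntervalTestResult] = []
    for label, start, end, means in jobs:
        cv = means[means.index.isin(case_ids)].to_numpy()
        uv = means[means.index.isin(ctrl_ids)].to_numpy()
        if len(cv) < 2 or len(uv) < 2:
            results.append(IntervalTestResult(
                label=label, start=start, end=end, biomarker=biomarker,
                mean_case=float(np.mean(cv)) if len(cv) else float("nan"),
                mean_control=float(np.mean(uv)) if len(uv) else float("nan"),
                t=float("nan"), p=float("nan"),
                n_case=len(cv), n_control=len(uv), skipped=True,
            ))
            continue
        if variant == "welch":
            t, p = _welch(cv, uv)
        else:
            t, p = _one_sample(cv, float(np.mean(uv)))
        results.append(IntervalTestResult(
            label=label, start=start, end=end, biomarker=biomarker,
            mean_case=float(np.mean(cv)), mean_control=float(np.mean(uv)),
            t=t, p=p, n_case=len(cv), n_control=len(uv),
        ))

    if adjust:
        keep = [r for r in results if not r.skipped]
        ps = np.array([r.p for r in keep])
        adj = _benjamini_hochberg(ps)
        adj_map = {id(r): a for r, a in zip(keep, adj)}
        results = [
            IntervalTestResult(**{**r.__dict__, "p_adjusted": adj_map.get(id(r))})
            for r in results
        ]
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def results_to_frame(results: list[IntervalTestResult]) -> pd.DataFrame:
    """Flatten test results to a tidy DataFrame (CSV-exportable)."""
    return pd.DataFrame([r.__dict__ for r in results])
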
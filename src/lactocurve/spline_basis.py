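"""Natural cubic spline basis on the peripartal time axis.

The longitudinal biomarker profiles are modelled as natural cubic splines of
the day relative to parturition: piecewise-cubic curves, twice continuously
differentiable at the knots, and constrained to be *linear* beyond the
boundary knots.  With ``m`` interior knots such a spline family has ``m + 1``
degrees of freedom (excluding the intercept), so the default layout of 7
interior knots — placed where structural metabolic changes are expected
(20 d and 7 d ante partum, parturition, then 7/14/25/50 d post partum) —
yields an 8-column design matrix over the fitted window of 27 d ante partum
to 80 d post partum.

The basis used here is the truncated-power construction (the same space as
R's ``splines::ns``); tests compare fitted *curves*, which are invariant to
the choice of basis within the space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SplineSpec",
    "DEFAULT_INTERIOR_KNOTS",
    "DEFAULT_BOUNDARY_KNOTS",
    "natural_cubic_basis",
    "thin_knots",
    "select_n_basis",
]

#: Interior knots (days relative to parturition) where structural changes in
#: the metabolite curves are expected.
DEFAULT_INTERIOR_KNOTS: tuple[float, ...] = (-20.0, -7.0, 0.0, 7.0, 14.0, 25.0, 50.0)

#: Boundary knots: the endpoints of the fitted window (27 d a.p. to 80 d p.p.).
DEFAULT_BOUNDARY_KNOTS: tuple[float, float] = (-27.0, 80.0)

#: Priority order in which interior knots are dropped when a smaller basis is
#: requested; parturition (day 0) is kept longest.
KNOT_DROP_ORDER: tuple[float, ...] = (-20.0, 50.0, 14.0, 25.0, -7.0, 7.0)


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout and size of a natural cubic spline family.

    ``n_basis`` is the number of basis columns (degrees of freedom excluding
    the intercept) and always equals the number of interior knots plus one.
    """

    interior_knots: tuple[float, ...] = DEFAULT_INTERIOR_KNOTS
    boundary_knots: tuple[float, float] = DEFAULT_BOUNDARY_KNOTS

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.interior_knots)
        bk = (float(self.boundary_knots[0]), float(self.boundary_knots[1]))
        object.__setattr__(self, "interior_knots", ik)
        object.__setattr__(self, "boundary_knots", bk)
        if bk[0] >= bk[1]:
            raise ValueError(f"boundary knots must be increasing, got {bk}")
        if list(ik) != sorted(set(ik)):
            raise ValueError(f"interior knots must be strictly increasing, got {ik}")
        if ik and (ik[0] <= bk[0] or ik[-1] >= bk[1]):
            raise ValueError(
                f"interior knots {ik} must lie strictly inside boundary {bk}"
            )

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + 1

    @property
    def all_knots(self) -> np.ndarray:
        """Boundary + interior knots in increasing order."""
        return np.asarray(
            (self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1])
        )


def natural_cubic_basis(days: Sequence[float], spec: SplineSpec | None = None) -> np.ndarray:
    """Evaluate the natural cubic spline design matrix.

    Parameters
    ----------
    days
        Evaluation points (days relative to parturition); any order, repeats
        allowed.
    spec
        Knot layout; defaults to the study layout (7 interior knots, 8 df).

    Returns
    -------
    ndarray of shape ``(len(days), spec.n_basis)``.  Columns span the natural
    cubic splines on the given knots: piecewise cubic, C2 at every knot, and
    linear at and beyond the boundary knots.  The intercept is *not* included.
    """
    if spec is None:
        spec = SplineSpec()
    x = np.asarray(days, dtype=float)
    if x.ndim != 1:
        x = np.ravel(x)
    knots = spec.all_knots  # xi_1 < ... < xi_K, K = m + 2
    K = len(knots)

    def d(k: int) -> np.ndarray:
        # truncated-power ratio d_k(x); cancelling cubic growth gives linear tails
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[K - 1], 0.0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def thin_knots(n_basis: int, spec: SplineSpec | None = None) -> SplineSpec:
    """Knot layout for a smaller basis, thinning the default interior knots.

    Knots are dropped in the fixed priority order ``KNOT_DROP_ORDER`` so that
    parturition (day 0) is retained longest.  ``n_basis`` interior knots kept
    = ``n_basis - 1``.
    """
    if spec is None:
        spec = SplineSpec()
    if not 2 <= n_basis <= spec.n_basis:
        raise ValueError(f"n_basis must be in [2, {spec.n_basis}], got {n_basis}")
    keep = list(spec.interior_knots)
    for knot in KNOT_DROP_ORDER:
        if len(keep) <= n_basis - 1:
            break
        if knot in keep:
            keep.remove(knot)
    # fall back to dropping from the outside in if custom layouts lack the
    # default knot values
    while len(keep) > n_basis - 1:
        keep.pop(0 if len(keep) % 2 == 0 else -1)
    return replace(spec, interior_knots=tuple(keep))


def select_n_basis(
    table,
    biomarker: str,
    candidates: Sequence[int],
    labels,
    spec: SplineSpec | None = None,
):
    """Choose the basis size by AIC over stage-2 mixed-model fits.

    Each candidate size uses the thinned knot layout from :func:`thin_knots`;
    the argmin-AIC candidate is returned, ties broken toward the smaller
    basis.  Candidates whose fit fails to converge are flagged and excluded.

    Returns
    -------
    (chosen_n_basis, dict candidate -> AIC or None if not converged)
    """
    from .mixed_model import fit_stage  # local import to avoid a cycle

    if spec is None:
        spec = SplineSpec()
    aics: dict[int, float | None] = {}
    for c in sorted(set(int(c) for c in candidates)):
        sub = thin_knots(c, spec)
        fit = fit_stage(table, biomarker, labels, sub, stage=2)
        aics[c] = fit.aic if fit.converged else None
    usable = {c: a for c, a in aics.items() if a is not None}
    if not usable:
        raise RuntimeError("no candidate basis size produced a converged fit")
    chosen = min(usable, key=lambda c: (usable[c], c))
    return chosen, aics
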
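"""Three-stage mixed-effects natural-spline model of log biomarker profiles.

Each biomarker is modelled on the natural-log scale over the window from 27 d
ante partum to 80 d post partum, with repeated measurements within a cow
correlated through per-cow random effects.  The model is built in three
strictly nested stages, all fitted by maximum likelihood (ML, not REML, so
likelihood-ratio tests on the fixed effects are valid):

* **stage 1** — spline fixed effects only, per-cow random intercept;
* **stage 2** — adds case status as a fixed effect on the intercept and on
  every spline coefficient (group x basis interaction);
* **stage 3** — stage 2 plus a per-cow *random* case effect: a scalar random
  shift expressed only by case cows, capturing cow-to-cow variation in how
  strongly the case profile is expressed.

With a random intercept (variance ``tau0^2``) and the scalar random case
shift (``taug^2``), the marginal covariance of cow *i*'s ``n_i`` responses is
compound symmetric, ``V_i = sigma^2 I + (tau0^2 + case_i * taug^2) J`` with
``J`` the all-ones matrix, so the likelihood has a closed form via the
Sherman-Morrison identity.  Fixed effects and the residual variance are
profiled out; the remaining one or two variance ratios are optimised on the
log scale, which enforces non-negativity by parameterisation.

Stage comparisons use the likelihood-ratio chi-square with degrees of freedom
from parameter-count differences.  Variance-component comparisons sit on the
boundary of the parameter space; the naive chi-square reference used here
(as in standard mixed-model ANOVA tables) is anti-conservative for them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core_data import CaseLabels, ObservationTable
from .spline_basis import SplineSpec, natural_cubic_basis

__all__ = [
    "ModelDesign",
    "MixedModelFit",
    "ModelComparison",
    "build_design",
    "loglik_at",
    "fit_stage",
    "compare_stages",
    "predict_curve",
]

_VARIANCE_FLOOR = 1e-300  # guards log() in the exact-interpolation limit
_LOG_RATIO_BOUNDS = (-14.0, 8.0)


@dataclass
class ModelDesign:
    """Response, fixed design and grouping for one stage on one biomarker."""

    y: np.ndarray                  # log response, stacked over cows
    X: np.ndarray                  # fixed-effects design
    cow_slices: list[slice]        # contiguous block per cow
    cow_ids: list[str]
    case: np.ndarray               # per-cow 0/1 case indicator
    stage: int
    fixed_names: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_cows(self) -> int:
        return len(self.cow_slices)


def build_design(
    table: ObservationTable,
    biomarker: str,
    labels: CaseLabels,
    spec: SplineSpec,
    stage: int,
    day_window: tuple[float, float] | None = None,
) -> ModelDesign:
    """Assemble the stacked log-response and fixed design for one stage.

    The fit is restricted to days inside ``day_window`` (default: the spline
    boundary knots).  Cows without a label (e.g. all-missing BHB) are
    dropped.
    """
    if stage not in (1, 2, 3):
        raise ValueError(f"stage must be 1, 2 or 3, got {stage}")
    lo, hi = day_window if day_window is not None else spec.boundary_knots
    df = table.df
    mask = (df["day"] >= lo) & (df["day"] <= hi) & df[biomarker].notna()
    mask &= df["cow_id"].isin(labels.is_case)
    sub = df[mask]
    if sub.empty:
        raise ValueError(f"no {biomarker} observations inside days [{lo}, {hi}]")

    y_parts, x_parts, slices, cow_ids, case = [], [], [], [], []
    pos = 0
    basis_names = [f"s{j + 1}" for j in range(spec.n_basis)]
    for cow_id, g in sub.groupby("cow_id", sort=True):
        yv = np.log(g[biomarker].to_numpy(dtype=float))
        B = natural_cubic_basis(g["day"].to_numpy(dtype=float), spec)
        base = np.column_stack([np.ones(len(yv)), B])
        is_case = float(labels.is_case[cow_id])
        if stage == 1:
            X = base
        else:
            X = np.column_stack([base, is_case * base])
        y_parts.append(yv)
        x_parts.append(X)
        slices.append(slice(pos, pos + len(yv)))
        cow_ids.append(cow_id)
        case.append(is_case)
        pos += len(yv)

    names = ["intercept", *basis_names]
    if stage >= 2:
        names += ["case", *[f"case:{b}" for b in basis_names]]
    return ModelDesign(
        y=np.concatenate(y_parts),
        X=np.vstack(x_parts),
        cow_slices=slices,
        cow_ids=cow_ids,
        case=np.asarray(case),
        stage=stage,
        fixed_names=names,
    )


def _cow_shrinkage(design: ModelDesign, lam0: float, lamg: float) -> np.ndarray:
    """Per-cow Sherman-Morrison weights c_i = u_i / (1 + n_i u_i)."""
    n_i = np.array([s.stop - s.start for s in design.cow_slices], dtype=float)
    u = lam0 + design.case * lamg
    return u / (1.0 + n_i * u)


def _profiled(design: ModelDesign, lam0: float, lamg: float):
    """GLS fixed effects, profiled residual variance and profiled loglik.

    ``lam0``/``lamg`` are variance ratios tau^2 / sigma^2.
    """
    n_i = np.array([s.stop - s.start for s in design.cow_slices], dtype=float)
    u = lam0 + design.case * lamg

    # whiten per cow: W_i = I - (u/(1+nu)) J has the analytic square root
    # I - ((1 - sqrt(1/(1+nu)))/n) J, so GLS reduces to plain least squares
    # on the transformed system (condition number not squared)
    Xw = design.X.copy()
    yw = design.y.copy()
    for i, s in enumerate(design.cow_slices):
        if u[i] == 0.0:
            continue
        n = n_i[i]
        shrink = (1.0 - math.sqrt(1.0 / (1.0 + n * u[i]))) / n
        Xw[s] -= shrink * design.X[s].sum(axis=0)
        yw[s] -= shrink * design.y[s].sum()
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)

    rss = float(np.sum((yw - Xw @ beta) ** 2))
    N = design.n_obs
    sigma2 = max(rss / N, _VARIANCE_FLOOR)
    logdet = float(np.sum(np.log1p(n_i * u)))
    ll = -0.5 * N * (math.log(2.0 * math.pi * sigma2) + 1.0) - 0.5 * logdet
    return beta, sigma2, ll


def loglik_at(
    design: ModelDesign,
    beta: np.ndarray,
    sigma2_resid: float,
    sigma2_intercept: float,
    sigma2_case: float = 0.0,
) -> float:
    """Exact marginal Gaussian log-likelihood at fully specified parameters.

    Integrates the per-cow random effects analytically; used both internally
    and as the quantity the direct multivariate-normal oracle must reproduce.
    """
    beta = np.asarray(beta, dtype=float)
    resid = design.y - design.X @ beta
    ll = 0.0
    for i, s in enumerate(design.cow_slices):
        r = resid[s]
        n = len(r)
        tau2 = sigma2_intercept + design.case[i] * sigma2_case
        u = tau2 / sigma2_resid
        c = u / (1.0 + n * u)
        quad = (r @ r - c * r.sum() ** 2) / sigma2_resid
        logdet = n * math.log(sigma2_resid) + math.log1p(n * u)
        ll += -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
    return float(ll)


@dataclass
class MixedModelFit:
    """ML estimates for one model stage on one biomarker."""

    stage: int
    biomarker: str
    beta: np.ndarray
    fixed_names: list[str]
    variance_components: dict[str, float]
    loglik: float
    n_params: int
    converged: bool
    spec: SplineSpec
    design: ModelDesign = field(repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def coef(self, name: str) -> float:
        return float(self.beta[self.fixed_names.index(name)])


def fit_stage(
    table: ObservationTable,
    biomarker: str,
    labels: CaseLabels,
    spec: SplineSpec | None = None,
    stage: int = 2,
    day_window: tuple[float, float] | None = None,
) -> MixedModelFit:
    """Fit one stage of the mixed-effects spline model by ML.

    Deterministic given the data: the one- or two-dimensional variance-ratio
    optimisation runs from a fixed grid of starting values and keeps the
    best.  Non-convergence is reported via ``converged=False`` rather than
    raised; a variance estimate collapsing to zero is reported, not fatal.
    """
    if spec is None:
        spec = SplineSpec()
    design = build_design(table, biomarker, labels, spec, stage, day_window)

    lo, hi = _LOG_RATIO_BOUNDS
    converged = True
    if stage in (1, 2):
        res = optimize.minimize_scalar(
            lambda t: -_profiled(design, math.exp(t), 0.0)[2],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(res.success)
        lam0, lamg = math.exp(res.x), 0.0
        # allow the no-random-effect boundary to win
        if _profiled(design, 0.0, 0.0)[2] > _profiled(design, lam0, 0.0)[2]:
            lam0 = 0.0
    else:
        best = None
        for t0, tg in ((0.0, -6.0), (-2.0, -2.0), (0.0, 0.0), (-6.0, 0.0)):
            res = optimize.minimize(
                lambda t: -_profiled(design, math.exp(t[0]), math.exp(t[1]))[2],
                x0=(t0, tg), method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success)
        lam0, lamg = math.exp(best.x[0]), math.exp(best.x[1])

    beta, sigma2, ll = _profiled(design, lam0, lamg)
    if sigma2 <= 1e-12:
        warnings.warn(
            f"{biomarker} stage {stage}: residual variance collapsed "
            "(exact-interpolation limit); variance components unreliable"
        )
    vc = {
        "sigma2_resid": sigma2,
        "sigma2_intercept": lam0 * sigma2,
    }
    n_params = design.X.shape[1] + 2
    if stage == 3:
        vc["sigma2_case"] = lamg * sigma2
        n_params += 1
    return MixedModelFit(
        stage=stage,
        biomarker=biomarker,
        beta=beta,
        fixed_names=design.fixed_names,
        variance_components=vc,
        loglik=ll,
        n_params=n_params,
        converged=converged,
        spec=spec,
        design=design,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of two nested ML fits."""

    label: str
    chi2: float
    df: int
    p: float


def _lrt(big: MixedModelFit, small: MixedModelFit, label: str) -> ModelComparison:
    if big.design.n_obs != small.design.n_obs or not np.allclose(
        np.sort(big.design.y), np.sort(small.design.y)
    ):
        raise ValueError(f"{label}: fits are not on the same observations")
    df = big.n_params - small.n_params
    if df < 0:
        raise ValueError(f"{label}: models not nested (df = {df})")
    chi2 = 2.0 * (big.loglik - small.loglik)
    if chi2 < -1e-6:
        warnings.warn(
            f"{label}: larger model has lower likelihood (chi2 = {chi2:.3g}); "
            "check convergence"
        )
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return ModelComparison(label=label, chi2=chi2, df=df, p=p)


def compare_stages(
    fit1: MixedModelFit, fit2: MixedModelFit, fit3: MixedModelFit | None = None
) -> list[ModelComparison]:
    """One-way-ANOVA-style comparison of the nested stages.

    Returns stage-2 vs 1, and with a stage-3 fit also 3 vs 2 and 3 vs 1.
    """
    out = [_lrt(fit2, fit1, "stage2_vs_stage1")]
    if fit3 is not None:
        out.append(_lrt(fit3, fit2, "stage3_vs_stage2"))
        out.append(_lrt(fit3, fit1, "stage3_vs_stage1"))
    return out


def predict_curve(
    fit: MixedModelFit,
    days: Sequence[float],
    group: str = "control",
) -> np.ndarray:
    """Population-level fitted curve on the natural concentration scale.

    ``group`` is ``"case"`` or ``"control"``; for a stage-1 fit both give the
    same curve (no group term).  Days outside the fitted window are refused.
    """
    days = np.asarray(days, dtype=float)
    lo, hi = fit.spec.boundary_knots
    if days.min() < lo or days.max() > hi:
        raise ValueError(f"prediction days must lie within [{lo}, {hi}]")
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    base = np.column_stack([np.ones(len(days)), natural_cubic_basis(days, fit.spec)])
    if fit.stage == 1:
        X = base
    else:
        is_case = 1.0 if group == "case" else 0.0
        X = np.column_stack([base, is_case * base])
    return np.exp(X @ fit.beta)
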
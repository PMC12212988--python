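"""Derivative-based tests of the developmental-constraints and adaptive-response hypotheses.

From the fitted quadratic surface

    y1 = γ + γ0·e0 + γd·|Δe| + γ00·e0² + γdd·|Δe|² + γ0d·e0·|Δe| + u

the developmental-constraints (DC) hypothesis predicts a positive marginal
effect of the developmental environment,

    ∂y1/∂e0 = γ0 + 2γ00·e0 + γ0d·|Δe| > 0,

while the adaptive-response (AR) hypothesis predicts a negative marginal
effect of the environment mismatch,

    ∂y1/∂|Δe| = γd + 2γdd·|Δe| + γ0d·e0 < 0.

Both derivatives are evaluated at a point (by default the sample means of e0
and |Δe|) and tested with delta-method standard errors from the
cluster-robust coefficient covariance, referring the statistic to a t
distribution with G−1 degrees of freedom (G = females).  DC is not testable
under the individual fixed effect, which absorbs e0 and e0².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    NotEstimableError,
    NotTestableError,
)
from .panel_builder import AnalysisTable
from .quadratic_model import (
    DesignMatrix,
    FitResult,
    ModelSpec,
    add_model_columns,
    build_design,
    fit_lpm,
)

HYPOTHESES = ("DC", "AR")

#: Predicted sign of the marginal effect under each hypothesis.
PREDICTED_DIRECTION = {"DC": "positive", "AR": "negative"}


@dataclass(frozen=True)
class EvalPoint:
    """Where the marginal effects are evaluated (environment units)."""

    e0: float
    abs_delta: float

    def __post_init__(self) -> None:
        if self.abs_delta < 0:
            raise ValueError("abs_delta must be non-negative")


def _default_point(fit: FitResult) -> EvalPoint:
    return EvalPoint(fit.env_means["e0"], fit.env_means["abs_delta"])


def _gradient(fit: FitResult, hypothesis: str, at: EvalPoint) -> pd.Series:
    """Delta-method gradient of the marginal effect over the fitted terms."""
    if hypothesis == "DC":
        weights = {"e0": 1.0, "e0_sq": 2.0 * at.e0, "e0_x_abs_delta": at.abs_delta}
    elif hypothesis == "AR":
        weights = {"abs_delta": 1.0, "abs_delta_sq": 2.0 * at.abs_delta,
                   "e0_x_abs_delta": at.e0}
    else:
        raise ValueError(f"hypothesis must be one of {HYPOTHESES}")
    missing = [t for t in weights if t not in fit.params.index]
    if missing:
        raise NotEstimableError(
            f"{hypothesis} derivative needs term(s) {missing} which are absorbed "
            f"or dropped under the {fit.fe_kind} fixed effect"
        )
    c = pd.Series(0.0, index=fit.params.index)
    for term, w in weights.items():
        c[term] = w
    return c


def dc_derivative(fit: FitResult, at: EvalPoint | None = None) -> float:
    """∂y1/∂e0 = γ0 + 2γ00·e0 + γ0d·|Δe| at the evaluation point."""
    at = at or _default_point(fit)
    return float(_gradient(fit, "DC", at) @ fit.params)


def ar_derivative(fit: FitResult, at: EvalPoint | None = None) -> float:
    """∂y1/∂|Δe| = γd + 2γdd·|Δe| + γ0d·e0 at the evaluation point."""
    at = at or _default_point(fit)
    return float(_gradient(fit, "AR", at) @ fit.params)


@dataclass
class DerivativeTestResult:
    """Marginal effect, delta-method SE, t statistic and two-sided p-value."""

    hypothesis: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    df: int
    eval_point: EvalPoint
    predicted_direction: str
    consistent_with_theory: bool
    alpha: float


def test_derivative(
    fit: FitResult,
    at: EvalPoint | None = None,
    hypothesis: str = "DC",
    alpha: float = 0.05,
) -> DerivativeTestResult:
    """Delta-method test of the DC or AR marginal effect.

    estimate = c·γ̂, se = sqrt(c' V c) with V the cluster-robust covariance;
    the two-sided p-value refers estimate/se to t(G−1).  The result is flagged
    consistent with theory iff the estimate's sign matches the hypothesis's
    predicted direction and p < alpha.
    """
    at = at or _default_point(fit)
    c = _gradient(fit, hypothesis, at)
    estimate = float(c @ fit.params)
    var = float(c @ fit.vcov.to_numpy() @ c)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        if estimate != 0.0:
            raise DegenerateVarianceError(
                f"{hypothesis} marginal effect {estimate:g} has zero variance"
            )
        statistic, p = 0.0, 1.0
    else:
        statistic = estimate / se
        p = 2.0 * float(stats.t.sf(abs(statistic), fit.df_t))
    direction = PREDICTED_DIRECTION[hypothesis]
    sign_ok = estimate > 0 if direction == "positive" else estimate < 0
    return DerivativeTestResult(
        hypothesis=hypothesis, estimate=estimate, se=se, statistic=statistic,
        p_value=p, df=fit.df_t, eval_point=at, predicted_direction=direction,
        consistent_with_theory=bool(sign_ok and p < alpha), alpha=alpha,
    )


def relative_to_absolute(relative_pct: float, baseline_mean_pct: float) -> float:
    """Translate a relative difference into absolute percentage points.

    A contrast that is, say, 13.18% of a 73.74% baseline outcome corresponds
    to an absolute difference of 13.18 × 73.74 / 100 = 9.72 percentage points
    (reported to two decimals).
    """
    if not (0.0 < baseline_mean_pct <= 100.0):
        raise ValueError("baseline mean must lie in (0, 100] percent")
    return round(relative_pct * baseline_mean_pct / 100.0, 2)


@dataclass
class ContrastResult:
    """Predicted-outcome contrast between two empirical percentiles."""

    variable: str
    lo_percentile: float
    hi_percentile: float
    value_lo: float
    value_hi: float
    predicted_lo: float
    predicted_hi: float
    relative_difference_pct: float
    absolute_difference_pct: float
    baseline_mean_pct: float
    adverse: str  # which end of the variable is the adverse condition
    loss_relative_pct: float  # adverse-outcome (1 - y) risk-ratio framing


def percentile_contrast(
    fit: FitResult,
    table: AnalysisTable,
    variable: str = "e0",
    lo: float = 10.0,
    hi: float = 90.0,
) -> ContrastResult:
    """Predicted outcome at the lo vs hi percentile of one environment variable.

    All other model inputs are held at sample means.  The relative difference
    is the good-minus-adverse predicted-probability gap expressed as a
    percentage of the sample mean outcome; the absolute difference rescales it
    back to percentage points (absolute = relative × baseline / 100).  For
    ``e0`` the adverse condition is the low percentile (worse developmental
    environment); for ``abs_delta`` it is the high percentile (larger
    mismatch).  A complementary adverse-outcome framing (the gap in predicted
    failure probability relative to the mean failure rate) is also reported.
    """
    if variable not in ("e0", "abs_delta"):
        raise ValueError("variable must be 'e0' or 'abs_delta'")
    for p in (lo, hi):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"percentile {p} outside [0, 100]")
    x = table.df[variable].to_numpy(dtype=float)
    v_lo, v_hi = float(np.percentile(x, lo)), float(np.percentile(x, hi))
    e0_bar = fit.env_means["e0"]
    d_bar = fit.env_means["abs_delta"]

    def contribution(v: float) -> float:
        if variable == "e0":
            terms = {"e0": v, "e0_sq": v * v, "e0_x_abs_delta": v * d_bar}
        else:
            terms = {"abs_delta": v, "abs_delta_sq": v * v, "e0_x_abs_delta": e0_bar * v}
        missing = [t for t in terms if t not in fit.params.index and terms[t] != 0.0]
        if variable == "e0" and "e0" not in fit.params.index:
            raise NotEstimableError(
                "e0 contrast not estimable: development terms absorbed by the "
                "individual fixed effect"
            )
        return sum(fit.params.get(t, 0.0) * val for t, val in terms.items())

    y_bar = fit.sample_stats["y_mean"]
    delta_lo = contribution(v_lo)
    delta_hi = contribution(v_hi)
    pred_lo = y_bar + (delta_lo - (delta_lo + delta_hi) / 2.0)
    pred_hi = y_bar + (delta_hi - (delta_lo + delta_hi) / 2.0)
    if variable == "e0":
        adverse, y_adv, y_good = "low", pred_lo, pred_hi
    else:
        adverse, y_adv, y_good = "high", pred_hi, pred_lo
    baseline_pct = 100.0 * y_bar
    gap = y_good - y_adv
    relative_pct = 100.0 * gap / y_bar if y_bar != 0 else 0.0
    absolute_pct = relative_pct * baseline_pct / 100.0
    loss_bar = 1.0 - y_bar
    loss_relative_pct = 100.0 * gap / loss_bar if loss_bar != 0 else 0.0
    return ContrastResult(
        variable=variable, lo_percentile=lo, hi_percentile=hi,
        value_lo=v_lo, value_hi=v_hi, predicted_lo=pred_lo, predicted_hi=pred_hi,
        relative_difference_pct=relative_pct, absolute_difference_pct=absolute_pct,
        baseline_mean_pct=baseline_pct, adverse=adverse,
        loss_relative_pct=loss_relative_pct,
    )


@dataclass
class AsymmetryResult:
    """Joint Wald test that positive and negative delta effects coincide."""

    statistic: float
    p_value: float
    df_num: int
    df_den: int
    construction: str
    params: pd.Series


def asymmetry_test(table: AnalysisTable, spec: ModelSpec) -> AsymmetryResult:
    """Test whether rises and falls in the environment act symmetrically.

    The |Δe| terms of the quadratic model are replaced by sign-split pieces
    Δ⁺ = max(Δ, 0) and Δ⁻ = max(−Δ, 0), each entering linearly and squared,
    and a joint 2-df cluster-robust Wald test compares the corresponding
    positive and negative coefficients (linear vs linear, quadratic vs
    quadratic).  The interaction term keeps |Δe|.  All deltas sharing one
    sign leave the contrast unidentified.
    """
    df = add_model_columns(table.df)
    delta = df["delta"].to_numpy(dtype=float)
    if (delta > 0).sum() == 0 or (delta < 0).sum() == 0:
        raise NotTestableError("all deltas share one sign; asymmetry is not testable")
    df["delta_pos"] = np.maximum(delta, 0.0)
    df["delta_neg"] = np.maximum(-delta, 0.0)
    df["delta_pos_sq"] = df["delta_pos"] ** 2
    df["delta_neg_sq"] = df["delta_neg"] ** 2

    split_terms = ["delta_pos", "delta_neg", "delta_pos_sq", "delta_neg_sq"]
    env_terms = [t for t in spec.environment_terms
                 if t not in ("abs_delta", "abs_delta_sq")]
    columns = split_terms + env_terms + list(spec.covariates)
    base = build_design(
        AnalysisTable(df.loc[:, list(table.df.columns)], table.outcome_kind,
                      table.environment_kind),
        spec,
    )
    X = df.loc[base.X.index if hasattr(base.X, "index") else slice(None), columns].astype(float)
    design = DesignMatrix(
        y=base.y, X=X.reset_index(drop=True), clusters=base.clusters, fe=base.fe,
        fe_kind=base.fe_kind, env_means=base.env_means,
        sample_stats=base.sample_stats, absorbed=base.absorbed, spec=spec,
    )
    fit = fit_lpm(design)
    pairs = [("delta_pos", "delta_neg"), ("delta_pos_sq", "delta_neg_sq")]
    rows = []
    for a, b in pairs:
        if a not in fit.params.index or b not in fit.params.index:
            raise NotTestableError(f"sign-split terms {a}/{b} not jointly estimable")
        r = pd.Series(0.0, index=fit.params.index)
        r[a], r[b] = 1.0, -1.0
        rows.append(r.to_numpy())
    R = np.vstack(rows)
    b = fit.params.to_numpy()
    V = fit.vcov.to_numpy()
    diff = R @ b
    mid = R @ V @ R.T
    q = R.shape[0]
    contrast_se = np.sqrt(np.clip(np.diag(mid), 0.0, None))
    if np.all(contrast_se < 1e-10):
        # (near-)zero residual variance: a perfectly fitted surface
        if float(np.abs(diff).max()) < 1e-8:
            W = 0.0
        else:
            raise DegenerateVarianceError("asymmetry contrast has singular variance")
    else:
        W = float(diff @ np.linalg.solve(mid, diff))
    F = W / q
    p = float(stats.f.sf(F, q, fit.df_t))
    return AsymmetryResult(
        statistic=F, p_value=p, df_num=q, df_den=fit.df_t,
        construction="sign-split linear and quadratic delta terms; joint 2-df "
                     "cluster-robust Wald test of pairwise equality",
        params=fit.params,
    )


def fit_quadratic(table: AnalysisTable, spec: ModelSpec) -> FitResult:
    """Convenience: build the design and fit the model in one call."""
    return fit_lpm(build_design(table, spec))
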
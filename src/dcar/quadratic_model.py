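"""Quadratic outcome regression with fixed effects and cluster-robust inference.

The adult outcome ``y1`` is approximated by a second-order expansion in the
developmental environment ``e0`` and the development/adulthood mismatch
``|Δe|``::

    y1 = γ + γ0·e0 + γd·|Δe| + γ00·e0² + γdd·|Δe|² + γ0d·e0·|Δe| + u

estimated as a linear probability model (least squares on the binary
outcome), with age, age² and group size covariates and either social-group or
individual (female) fixed effects.  Standard errors cluster on female
identity with the CR1 small-sample factor G/(G−1)·(N−1)/(N−K), and test
statistics refer to a t distribution with G−1 degrees of freedom (G =
clusters).

Under the individual fixed effect the development-only terms ``e0`` and
``e0²`` are absorbed (each female has a single developmental environment) and
are flagged as not estimable rather than reported as zero; the interaction
``e0·|Δe|`` varies within females and is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .errors import DcarError, InsufficientClustersError
from .panel_builder import AnalysisTable

#: Environment terms of the quadratic model, in canonical order.
ENV_TERMS = ("e0", "abs_delta", "e0_sq", "abs_delta_sq", "e0_x_abs_delta")

#: Environment terms absorbed by the individual fixed effect.
DEVELOPMENT_ONLY_TERMS = ("e0", "e0_sq")

DEFAULT_COVARIATES = ("age", "age_sq", "group_size")

FIXED_EFFECTS = ("group", "individual", "none")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: outcome, environment, fixed effect, covariates."""

    outcome_kind: str | None = None
    environment_kind: str | None = None
    fixed_effect: str = "group"
    covariates: Sequence[str] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.fixed_effect not in FIXED_EFFECTS:
            raise ValueError(f"fixed_effect must be one of {FIXED_EFFECTS}")

    @property
    def environment_terms(self) -> tuple[str, ...]:
        """Estimable environment columns under this fixed-effect choice."""
        if self.fixed_effect == "individual":
            return tuple(t for t in ENV_TERMS if t not in DEVELOPMENT_ONLY_TERMS)
        return ENV_TERMS


@dataclass
class DesignMatrix:
    """Aligned response, predictors, cluster ids and fixed-effect ids."""

    y: np.ndarray
    X: pd.DataFrame
    clusters: np.ndarray
    fe: np.ndarray | None
    fe_kind: str
    env_means: dict
    sample_stats: dict
    absorbed: tuple[str, ...] = ()
    n_singletons_dropped: int = 0
    spec: ModelSpec | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.clusters))


def add_model_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append the squared and interaction environment columns."""
    out = df.copy()
    out["e0_sq"] = out["e0"] ** 2
    out["abs_delta_sq"] = out["abs_delta"] ** 2
    out["e0_x_abs_delta"] = out["e0"] * out["abs_delta"]
    if "age_sq" not in out.columns and "age" in out.columns:
        out["age_sq"] = out["age"] ** 2
    return out


def build_design(table: AnalysisTable, spec: ModelSpec) -> DesignMatrix:
    """Assemble the regression design for an analysis table.

    Columns are the estimable environment terms followed by the covariates;
    fixed effects are kept as an id vector and absorbed at fit time.  Clusters
    are female ids.  Under the individual fixed effect, females contributing a
    single observation are uninformative after demeaning and are dropped (with
    a warning).  Fewer than two clusters make clustered inference impossible.
    """
    if len(table.df) == 0:
        raise ValueError("empty analysis table")
    df = add_model_columns(table.df)
    if spec.fixed_effect == "individual":
        sizes = df.groupby("female_id")["outcome"].transform("size")
        n_single = int((sizes == 1).sum())
        if n_single:
            warnings.warn(
                f"dropping {n_single} singleton female(s) under individual fixed effect",
                stacklevel=2,
            )
            df = df.loc[sizes > 1]
    else:
        n_single = 0
    if df["female_id"].nunique() < 2:
        raise InsufficientClustersError(
            "clustered inference requires at least 2 females (clusters)"
        )
    columns = list(spec.environment_terms) + list(spec.covariates)
    absorbed = tuple(t for t in ENV_TERMS if t not in spec.environment_terms)
    X = df.loc[:, columns].astype(float)
    if spec.fixed_effect == "none":
        X.insert(0, "intercept", 1.0)
        fe = None
    elif spec.fixed_effect == "group":
        fe = df["group_id"].to_numpy()
    else:
        fe = df["female_id"].to_numpy()
    y = df["outcome"].to_numpy(dtype=float)
    env_means = {
        "e0": float(df["e0"].mean()),
        "abs_delta": float(df["abs_delta"].mean()),
    }
    sample_stats = {
        "y_mean": float(y.mean()), "y_sd": float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        "e0_mean": env_means["e0"], "e0_sd": float(df["e0"].std(ddof=1)),
        "abs_delta_mean": env_means["abs_delta"],
        "abs_delta_sd": float(df["abs_delta"].std(ddof=1)),
        "n_obs": int(len(df)), "n_females": int(df["female_id"].nunique()),
    }
    return DesignMatrix(
        y=y, X=X, clusters=df["female_id"].to_numpy(), fe=fe,
        fe_kind=spec.fixed_effect, env_means=env_means, sample_stats=sample_stats,
        absorbed=absorbed, n_singletons_dropped=n_single, spec=spec,
    )


@dataclass
class FitResult:
    """Least-squares estimates of the quadratic model with clustering metadata."""

    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int
    k_params: int
    cluster_var: str
    fe_kind: str
    env_means: dict
    sample_stats: dict
    absorbed: tuple[str, ...]
    dropped_collinear: tuple[str, ...]
    fe_effects: pd.Series | None
    residuals: np.ndarray = field(repr=False)
    _Xd: np.ndarray = field(repr=False, default=None)
    _clusters: np.ndarray = field(repr=False, default=None)

    @property
    def df_t(self) -> int:
        """Degrees of freedom of the t reference distribution (G − 1)."""
        return self.n_clusters - 1

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index)

    def tidy(self) -> pd.DataFrame:
        """Coefficient table including absorbed (not-estimable) terms."""
        rows = [
            {"term": t, "estimate": self.params[t], "se": s, "absorbed": False}
            for t, s in self.se().items()
        ]
        rows += [
            {"term": t, "estimate": np.nan, "se": np.nan, "absorbed": True}
            for t in self.absorbed
        ]
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "absorbed"])


def _demean(M: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Subtract level means (within transformation) column-wise."""
    if M.ndim == 1:
        M = M[:, None]
        squeeze = True
    else:
        squeeze = False
    sums = np.zeros((n_levels, M.shape[1]))
    np.add.at(sums, codes, M)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    means = sums / counts[:, None]
    out = M - means[codes]
    return out[:, 0] if squeeze else out


def _drop_collinear(Xd: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Pivoted-QR elimination of rank-deficient columns, reported by name."""
    if Xd.shape[1] == 0:
        return Xd, names, ()
    _, R, piv = sla.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Xd.shape) * np.finfo(float).eps * (diag[0] if diag.size and diag[0] > 0 else 1.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = tuple(names[j] for j in sorted(piv[rank:]))
    if dropped:
        warnings.warn(f"dropping collinear column(s): {dropped}", stacklevel=3)
    return Xd[:, keep], [names[j] for j in keep], dropped


def fit_lpm(design: DesignMatrix, method: str = "demean") -> FitResult:
    """Fit the linear probability model by least squares.

    ``method='demean'`` absorbs fixed effects by the within transformation;
    ``method='dummies'`` estimates them as explicit indicator columns.  Slope
    coefficients agree between the two to numerical precision.  Cluster-robust
    covariance (CR1, clustered on female id) is attached to the result.
    """
    if method not in ("demean", "dummies"):
        raise ValueError("method must be 'demean' or 'dummies'")
    X = design.X.to_numpy(dtype=float)
    names = list(design.X.columns)
    y = design.y.astype(float)
    if design.fe is not None:
        fe_codes, fe_levels = pd.factorize(design.fe)
        n_fe = len(fe_levels)
    else:
        fe_codes, fe_levels, n_fe = None, None, 0

    if design.fe is None:
        Xw, yw = X, y
    elif method == "demean":
        Xw = _demean(X, fe_codes, n_fe)
        yw = _demean(y, fe_codes, n_fe)
    else:  # dummies
        D = np.zeros((len(y), n_fe))
        D[np.arange(len(y)), fe_codes] = 1.0
        Xw, yw = np.hstack([X, D]), y

    if method == "dummies" and design.fe is not None:
        all_names = names + [f"_fe_{lv}" for lv in fe_levels]
        Xk, kept_all, dropped = _drop_collinear(Xw, all_names)
        beta_all, *_ = np.linalg.lstsq(Xk, yw, rcond=None)
        slope_idx = [i for i, n in enumerate(kept_all) if not n.startswith("_fe_")]
        kept = [kept_all[i] for i in slope_idx]
        beta = beta_all[slope_idx]
        resid = yw - Xk @ beta_all
        dropped = tuple(d for d in dropped if not d.startswith("_fe_"))
        Xd = _demean(X[:, [names.index(n) for n in kept]], fe_codes, n_fe)
        fe_eff = pd.Series(
            {str(lv): float(b) for lv, b in zip(fe_levels, beta_all[len(slope_idx):])}
        ) if len(kept_all) > len(slope_idx) else None
    else:
        Xk, kept, dropped = _drop_collinear(Xw, names)
        beta, *_ = np.linalg.lstsq(Xk, yw, rcond=None)
        resid = yw - Xk @ beta
        Xd = Xk
        if design.fe is not None:
            kept_idx = [names.index(n) for n in kept]
            ybar = np.bincount(fe_codes, weights=y) / np.bincount(fe_codes)
            xbar = np.vstack([
                np.bincount(fe_codes, weights=X[:, j]) / np.bincount(fe_codes)
                for j in kept_idx
            ]).T
            fe_eff = pd.Series(
                {str(lv): float(a) for lv, a in zip(fe_levels, ybar - xbar @ beta)}
            )
        else:
            fe_eff = None

    k_params = len(kept) + n_fe
    params = pd.Series(beta, index=kept, dtype=float)
    absorbed = tuple(design.absorbed) + tuple(d for d in dropped)
    fit = FitResult(
        params=params, vcov=None, n_obs=design.n_obs,
        n_clusters=design.n_clusters, k_params=k_params, cluster_var="female_id",
        fe_kind=design.fe_kind, env_means=dict(design.env_means),
        sample_stats=dict(design.sample_stats), absorbed=absorbed,
        dropped_collinear=dropped, fe_effects=fe_eff, residuals=resid,
        _Xd=Xd, _clusters=design.clusters,
    )
    fit.vcov = cluster_vcov(fit)
    return fit


def cluster_vcov(fit: FitResult, design: DesignMatrix | None = None) -> pd.DataFrame:
    """One-way cluster-robust (CR1) sandwich covariance of the slope terms.

    ``(X'X)^{-1} [Σ_g (X_g'u_g)(X_g'u_g)'] (X'X)^{-1}`` scaled by the
    small-sample factor ``G/(G−1) · (N−1)/(N−K)``, where K counts both slope
    and absorbed fixed-effect parameters.  X here is the within-transformed
    design, whose slope sandwich equals the dummy-encoded one exactly.
    """
    Xd = fit._Xd
    u = fit.residuals
    clusters = design.clusters if design is not None else fit._clusters
    codes, levels = pd.factorize(clusters)
    G = len(levels)
    if G < 2:
        raise InsufficientClustersError("cluster-robust vcov requires >= 2 clusters")
    N, p = Xd.shape
    XtX = Xd.T @ Xd
    cond = np.linalg.cond(XtX) if p else 0.0
    if p and cond > 1e12:
        raise DcarError(
            f"singular bread matrix (condition number {cond:.3e}); "
            "drop collinear terms before computing the sandwich"
        )
    bread = np.linalg.inv(XtX) if p else np.zeros((0, 0))
    scores = Xd * u[:, None]
    S = np.zeros((G, p))
    np.add.at(S, codes, scores)
    meat = S.T @ S
    if N - fit.k_params <= 0:
        raise DcarError("no residual degrees of freedom for the CR1 correction")
    c = (G / (G - 1)) * ((N - 1) / (N - fit.k_params))
    V = c * bread @ meat @ bread
    V = (V + V.T) / 2.0
    return pd.DataFrame(V, index=fit.params.index, columns=fit.params.index)
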
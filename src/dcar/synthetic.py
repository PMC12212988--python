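"""Synthetic longitudinal fertility panels and power/size simulation studies.

The generator emulates the statistical structure of the real analysis tables:
a developmental environment ``e0`` drawn once per female (uniform on [0, 1]
for rank-like environments; right-skewed positive with mean ≈ 28.8 mm/month
for rainfall-like environments), adult environments ``e1`` drawn per
observation with a configurable correlation to ``e0`` (Gaussian copula),
within-female repeated observations with female and group random intercepts,
and age/group-size covariates.  Outcomes follow the quadratic surface

    η = γ + γ0·e0 + γd·|Δe| + γ00·e0² + γdd·|Δe|² + γ0d·e0·|Δe| + covariates

with one of three outcome links:

* ``linear-clipped`` — Bernoulli with success probability clip(η + ε, 0, 1)
  (the analysis model's own probability scale; the default for fertility-like
  panels);
* ``logistic`` — Bernoulli(expit(η + ε)), for misspecification experiments;
* ``gaussian`` — continuous y = η + ε, for power and recovery studies where
  the generative model is exactly the fitted regression with Gaussian noise.

Default panel parameters mirror the conception analysis: 295 females, ≈28
cycling-month observations each, mean outcome 0.137, uniform rank-like e0
(sd ≈ 0.29) and corr(e0, e1) = 0.71.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .errors import DcarError
from .panel_builder import AnalysisTable
from .quadratic_model import ModelSpec, build_design, fit_lpm
from . import hypothesis_tests as ht

GAMMA_KEYS = ("intercept", "e0", "abs_delta", "e0_sq", "abs_delta_sq", "e0_x_abs_delta")
COVARIATE_KEYS = ("age", "age_sq", "group_size")
LINKS = ("linear-clipped", "logistic", "gaussian")

#: Mean development rainfall (mm/month) the rain-like marginal is scaled to.
RAIN_MEAN = 28.8
_RAIN_LOG_SD = 0.45


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic panel.

    ``gamma`` maps quadratic-model coefficient names to true values; with
    ``standardize_gammas`` (default) they apply to empirically z-scored
    environment columns, so e.g. ``{"e0": 0.5}`` means half an outcome unit
    per standard deviation of e0.  ``rho_e0_e1`` is the target Pearson
    correlation between developmental and adult environments (0.71 matches
    the rank infant-survival data).
    """

    n_females: int = 295
    obs_per_female: int | tuple[int, int] = (20, 37)
    n_groups: int = 7
    gamma: Mapping[str, float] = field(default_factory=lambda: {"intercept": 0.137})
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    e0_distribution: str = "rank"
    rho_e0_e1: float = 0.71
    female_sd: float = 0.05
    group_sd: float = 0.02
    noise_sd: float = 0.05
    outcome_link: str = "linear-clipped"
    standardize_gammas: bool = True
    outcome_kind: str = "conception"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 1 or self.n_groups < 1:
            raise ValueError("counts must be >= 1")
        if not -1.0 <= self.rho_e0_e1 <= 1.0:
            raise ValueError("rho_e0_e1 must lie in [-1, 1]")
        for sd in (self.female_sd, self.group_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.e0_distribution not in ("rank", "rain"):
            raise ValueError("e0_distribution must be 'rank' or 'rain'")
        if self.outcome_link not in LINKS:
            raise ValueError(f"outcome_link must be one of {LINKS}")
        bad = set(self.gamma) - set(GAMMA_KEYS)
        if bad:
            raise ValueError(f"unknown gamma keys: {sorted(bad)}")
        bad = set(self.covariate_effects) - set(COVARIATE_KEYS)
        if bad:
            raise ValueError(f"unknown covariate-effect keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "obs_per_female" in d and isinstance(d["obs_per_female"], (list, tuple)):
            d["obs_per_female"] = tuple(d["obs_per_female"])
        return cls(**d)


@dataclass
class EnvironmentDraw:
    """Per-female e0 and per-observation e1 with achieved-correlation metadata."""

    e0: np.ndarray          # (n_females,)
    e1: np.ndarray          # (n_obs,)
    female_index: np.ndarray  # (n_obs,) -> row of e0
    achieved_rho: float
    clip_fraction: float


def _obs_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    o = config.obs_per_female
    if isinstance(o, int):
        return np.full(config.n_females, o)
    lo, hi = o
    return rng.integers(lo, hi + 1, size=config.n_females)


def _marginal(z: np.ndarray, distribution: str) -> np.ndarray:
    if distribution == "rank":
        return ndtr(z)  # uniform marginal on [0, 1]
    mu = np.log(RAIN_MEAN) - _RAIN_LOG_SD**2 / 2.0
    return np.exp(mu + _RAIN_LOG_SD * z)


def simulate_environment(
    config: SyntheticConfig, rng: np.random.Generator | None = None,
    obs_counts: np.ndarray | None = None,
) -> EnvironmentDraw:
    """Draw e0 once per female and e1 per observation via a Gaussian copula.

    For the uniform rank marginal the latent correlation is adjusted
    (ρ* = 2·sin(πρ/6)) so the *Pearson* correlation of the rank values hits
    the configured target.  Rank values need no clipping (the copula maps
    into [0, 1]); the clip fraction is reported for other marginals.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    counts = obs_counts if obs_counts is not None else _obs_counts(config, rng)
    rho = config.rho_e0_e1
    if config.e0_distribution == "rank" and abs(rho) < 1.0:
        rho_latent = 2.0 * np.sin(np.pi * rho / 6.0)
    else:
        rho_latent = rho
    z0 = rng.standard_normal(config.n_females)
    female_index = np.repeat(np.arange(config.n_females), counts)
    eps = rng.standard_normal(len(female_index))
    if rho_latent == 1.0:
        z1 = z0[female_index]
    else:
        z1 = rho_latent * z0[female_index] + np.sqrt(1.0 - rho_latent**2) * eps
    e0 = _marginal(z0, config.e0_distribution)
    e1 = _marginal(z1, config.e0_distribution)
    clip_fraction = 0.0
    if config.e0_distribution == "rank":
        before = e1.copy()
        e1 = np.clip(e1, 0.0, 1.0)
        clip_fraction = float(np.mean(before != e1))
    achieved = (
        float(np.corrcoef(e0[female_index], e1)[0, 1])
        if len(e1) > 1 and np.std(e1) > 0 and np.std(e0[female_index]) > 0
        else float("nan")
    )
    if abs(rho) < 1.0 and np.isfinite(achieved) and abs(achieved - rho) > 0.1:
        warnings.warn(
            f"achieved corr(e0, e1) = {achieved:.3f} differs from target {rho:.3f}",
            stacklevel=2,
        )
    return EnvironmentDraw(e0, e1, female_index, achieved, clip_fraction)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_panel(config: SyntheticConfig) -> AnalysisTable:
    """Generate one analysis table from the quadratic generative model.

    Identical config and seed give bit-identical panels.  A perfect e0/e1
    correlation leaves no mismatch variation and triggers a degenerate-design
    warning; a linear-clipped link pushing more than 20% of latent
    probabilities outside [0, 1] triggers a configuration warning.
    """
    rng = np.random.default_rng(config.seed)
    counts = _obs_counts(config, rng)
    env = simulate_environment(config, rng, obs_counts=counts)
    fi = env.female_index
    n = len(fi)

    e0_obs = env.e0[fi]
    delta = env.e1 - e0_obs
    abs_delta = np.abs(delta)
    if np.all(abs_delta == 0.0):
        warnings.warn(
            "rho_e0_e1 = 1 leaves no environment-mismatch variation; "
            "AR terms will be degenerate", stacklevel=2,
        )

    groups = rng.integers(0, config.n_groups, size=config.n_females)
    age_start = rng.uniform(5.0, 18.0, size=config.n_females)
    obs_rank = np.concatenate([np.arange(c) for c in counts]) if n else np.array([])
    age = age_start[fi] + 0.25 * obs_rank
    group_size = np.clip(rng.normal(35.0, 10.0, size=n), 8.0, 100.0)

    terms = {
        "e0": e0_obs, "abs_delta": abs_delta, "e0_sq": e0_obs**2,
        "abs_delta_sq": abs_delta**2, "e0_x_abs_delta": e0_obs * abs_delta,
    }
    covs = {"age": age, "age_sq": age**2, "group_size": group_size}
    gamma = dict(config.gamma)
    eta = np.full(n, gamma.get("intercept", 0.0))
    for key, x in terms.items():
        g = gamma.get(key, 0.0)
        if g:
            base = {"e0": e0_obs, "abs_delta": abs_delta}
            if config.standardize_gammas:
                if key in base:
                    x = _zscore(base[key])
                elif key.endswith("_sq"):
                    x = _zscore(base[key[:-3]]) ** 2
                else:
                    x = _zscore(e0_obs) * _zscore(abs_delta)
            eta = eta + g * x
    for key, x in covs.items():
        g = config.covariate_effects.get(key, 0.0)
        if g:
            eta = eta + g * (_zscore(x) if config.standardize_gammas else x)

    female_eff = rng.normal(0.0, config.female_sd, size=config.n_females)[fi]
    group_eff = rng.normal(0.0, config.group_sd, size=config.n_groups)[groups][fi]
    noise = rng.normal(0.0, config.noise_sd, size=n)
    latent = eta + female_eff + group_eff + noise

    if config.outcome_link == "gaussian":
        y = latent
    elif config.outcome_link == "linear-clipped":
        outside = float(np.mean((latent < 0.0) | (latent > 1.0)))
        if outside > 0.20:
            warnings.warn(
                f"{outside:.0%} of latent probabilities fall outside [0, 1] "
                "under the linear-clipped link", stacklevel=2,
            )
        y = rng.binomial(1, np.clip(latent, 0.0, 1.0)).astype(float)
    else:
        y = rng.binomial(1, expit(latent)).astype(float)

    df = pd.DataFrame(
        {
            "female_id": np.array([f"f{j:04d}" for j in range(config.n_females)])[fi],
            "group_id": np.array([f"g{j}" for j in range(config.n_groups)])[groups][fi],
            "month": [f"m{int(k):03d}" for k in obs_rank],
            "outcome": y,
            "e0": e0_obs,
            "e1": env.e1,
            "delta": delta,
            "abs_delta": abs_delta,
            "age": age,
            "age_sq": age**2,
            "group_size": group_size,
        }
    )
    return AnalysisTable(df, config.outcome_kind, "rank" if config.e0_distribution == "rank" else "rain")


# ---------------------------------------------------------------------------
# preset configurations (the study conditions for the simulation claims)
# ---------------------------------------------------------------------------


def strong_dc_config(seed: int = 0) -> SyntheticConfig:
    """Strong developmental-constraints regime: +0.5 per sd of e0, Gaussian noise 0.5."""
    return SyntheticConfig(
        n_females=300, obs_per_female=10, n_groups=6,
        gamma={"intercept": 0.3, "e0": 0.5},
        noise_sd=0.5, female_sd=0.1, group_sd=0.05,
        outcome_link="gaussian", seed=seed,
    )


def strong_ar_config(seed: int = 0) -> SyntheticConfig:
    """Strong adaptive-response regime: −0.5 per sd of |Δe|, Gaussian noise 0.5."""
    return SyntheticConfig(
        n_females=300, obs_per_female=10, n_groups=6,
        gamma={"intercept": 0.3, "abs_delta": -0.5},
        noise_sd=0.5, female_sd=0.1, group_sd=0.05,
        outcome_link="gaussian", seed=seed,
    )


def null_config(seed: int = 0, n_females: int = 150) -> SyntheticConfig:
    """All environment coefficients zero: the size-control regime."""
    return SyntheticConfig(
        n_females=n_females, obs_per_female=(8, 12), n_groups=6,
        gamma={"intercept": 0.3},
        noise_sd=0.05, female_sd=0.05, group_sd=0.02,
        outcome_link="linear-clipped", seed=seed,
    )


def recovery_config(seed: int = 0, n_females: int = 200) -> SyntheticConfig:
    """Known raw-scale coefficients for parameter-recovery checks (n = 2000)."""
    return SyntheticConfig(
        n_females=n_females, obs_per_female=10, n_groups=6,
        gamma={
            "intercept": 0.2, "e0": 0.4, "abs_delta": -0.3,
            "e0_sq": -0.2, "abs_delta_sq": 0.15, "e0_x_abs_delta": 0.1,
        },
        noise_sd=0.3, female_sd=0.1, group_sd=0.05,
        outcome_link="gaussian", standardize_gammas=False, seed=seed,
    )


# ---------------------------------------------------------------------------
# power / size studies
# ---------------------------------------------------------------------------

#: Fixed-effect specification each hypothesis is tested under by default:
#: DC requires the group fixed effect; AR uses the within-female comparison.
DEFAULT_FE = {"DC": "group", "AR": "individual"}


@dataclass
class PowerStudyResult:
    """Rejection fractions of the derivative tests over simulation replicates."""

    rejection_fraction: dict
    mc_se: dict
    n_reps: int
    n_skipped: int
    alpha: float
    config: SyntheticConfig


def run_power_study(
    config: SyntheticConfig,
    n_reps: int,
    alpha: float = 0.05,
    hypotheses: tuple[str, ...] = ("DC", "AR"),
    fe_for: Mapping[str, str] | None = None,
    directional: bool = True,
) -> PowerStudyResult:
    """Simulate, fit and test repeatedly; report rejection rates.

    With ``directional`` (the sensitivity criterion) a replicate rejects when
    the derivative test at sample means is both significant at ``alpha``
    (two-sided) and signed in the hypothesis's predicted direction; without
    it (the size criterion) significance alone counts.  Replicate r uses seed
    ``config.seed + r``.  Failed replicates are skipped and counted; more
    than 5% failures abort the run.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    fe_for = dict(DEFAULT_FE, **(fe_for or {}))
    hits = {h: 0 for h in hypotheses}
    done = 0
    skipped = 0
    for r in range(n_reps):
        cfg = replace(config, seed=config.seed + r)
        try:
            table = simulate_panel(cfg)
            for h in hypotheses:
                spec = ModelSpec(
                    outcome_kind=table.outcome_kind,
                    environment_kind=table.environment_kind,
                    fixed_effect=fe_for[h],
                )
                fit = fit_lpm(build_design(table, spec))
                res = ht.test_derivative(fit, hypothesis=h, alpha=alpha)
                rejected = (
                    res.consistent_with_theory if directional else res.p_value < alpha
                )
                hits[h] += int(rejected)
        except DcarError:
            skipped += 1
            continue
        done += 1
    if done == 0 or skipped / n_reps > 0.05:
        raise DcarError(f"{skipped}/{n_reps} replicates failed")
    frac = {h: hits[h] / done for h in hypotheses}
    mc = {h: float(np.sqrt(f * (1 - f) / done)) for h, f in frac.items()}
    return PowerStudyResult(
        rejection_fraction=frac, mc_se=mc, n_reps=done, n_skipped=skipped,
        alpha=alpha, config=config,
    )
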
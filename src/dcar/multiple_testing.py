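"""Sharpened two-stage FDR q-values for a family of hypothesis tests.

The two-stage step-up procedure (Benjamini–Krieger–Yekutieli) first runs a
step-up pass at level q' = q/(1+q) to estimate the number of true nulls
m̂0 = m − r1 (r1 = first-stage rejections), then re-runs the step-up at the
sharpened level q'·m/m̂0.  The *sharpened q-value* of a test is the smallest
level on a fixed grid at which the two-stage procedure rejects it; because
the estimated null proportion can exceed one-stage thresholds, a q-value can
be smaller than its p-value.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_GRID_STEP = 0.001


def _as_series(pvals) -> pd.Series:
    s = pd.Series(pvals, dtype=float)
    if s.index.has_duplicates:
        raise ValueError("test labels must be unique")
    vals = s.to_numpy()
    if len(s) and (np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return s


def _stepup_count(p_sorted: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """r(level) = max{i : p_(i) <= i * level / m} for each level (vectorized)."""
    m = len(p_sorted)
    i = np.arange(1, m + 1)[:, None]
    hit = p_sorted[:, None] <= i * levels[None, :] / m
    return np.where(hit.any(axis=0), (hit * i).max(axis=0), 0)


def _two_stage_counts(p_sorted: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Final two-stage rejection count at each level."""
    m = len(p_sorted)
    q1 = levels / (1.0 + levels)
    r1 = _stepup_count(p_sorted, q1)
    m0 = m - r1
    with np.errstate(divide="ignore"):
        q2 = np.where(m0 > 0, q1 * m / np.maximum(m0, 1), np.inf)
    r2 = np.where(
        r1 == 0, 0,
        np.where(r1 == m, m, _stepup_count(p_sorted, np.where(np.isfinite(q2), q2, 1.0))),
    )
    return r2


def bky_two_stage(pvals: Mapping[str, float], q: float) -> set:
    """Labels rejected by the two-stage step-up procedure at FDR level ``q``."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    s = _as_series(pvals)
    if len(s) == 0:
        return set()
    order = np.argsort(s.to_numpy(), kind="stable")
    p_sorted = s.to_numpy()[order]
    r = int(_two_stage_counts(p_sorted, np.array([q]))[0])
    return set(s.index[order[:r]])


def sharpened_qvalues(
    pvals: Mapping[str, float], grid_step: float = DEFAULT_GRID_STEP
) -> pd.Series:
    """Sharpened q-value of each test: the smallest grid level that rejects it.

    The grid is {grid_step, 2·grid_step, …, 1 − grid_step}; tests never
    rejected on the grid receive q = 1.  q-values are monotone in p within a
    family.
    """
    s = _as_series(pvals)
    if len(s) == 0:
        return pd.Series(dtype=float)
    levels = np.arange(grid_step, 1.0, grid_step)
    order = np.argsort(s.to_numpy(), kind="stable")
    p_sorted = s.to_numpy()[order]
    r2 = _two_stage_counts(p_sorted, levels)
    m = len(s)
    q_sorted = np.ones(m)
    for i in range(m):  # position i (0-based) rejected where r2 >= i+1
        ok = levels[r2 >= i + 1]
        if len(ok):
            q_sorted[i] = ok[0]
    # enforce ties: equal p-values share the smallest q among them
    for i in range(m - 1, 0, -1):
        if p_sorted[i - 1] == p_sorted[i]:
            q_sorted[i - 1] = min(q_sorted[i - 1], q_sorted[i])
    out = np.empty(m)
    out[order] = q_sorted
    return pd.Series(out, index=s.index)
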
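"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_rain_mean(dates, depths, window_start, months: int) -> float:
    """Day-by-day summation over the half-open calendar window, divided by months."""
    start = pd.Timestamp(window_start)
    end = start + pd.DateOffset(months=months)
    total = 0.0
    for d, x in zip(dates, depths):
        if start <= pd.Timestamp(d) < end:
            total += x
    return total / months


def brute_sandwich(X: np.ndarray, u: np.ndarray, clusters, k_params: int) -> np.ndarray:
    """CR1 cluster sandwich assembled cluster by cluster with explicit outer products."""
    X = np.asarray(X, dtype=float)
    u = np.asarray(u, dtype=float)
    labels = list(dict.fromkeys(clusters))
    G = len(labels)
    N, p = X.shape
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((p, p))
    for g in labels:
        idx = [i for i, c in enumerate(clusters) if c == g]
        s = np.zeros(p)
        for i in idx:
            s = s + X[i] * u[i]
        meat = meat + np.outer(s, s)
    c = (G / (G - 1)) * ((N - 1) / (N - k_params))
    return c * bread @ meat @ bread


def finite_difference(surface, x0: float, step: float = 1e-5) -> float:
    """Central finite difference of a scalar function at x0."""
    return (surface(x0 + step) - surface(x0 - step)) / (2.0 * step)


def brute_bky(pvals: dict, q: float) -> set:
    """Two-stage step-up re-implemented with plain loops."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    if m == 0:
        return set()
    q1 = q / (1.0 + q)

    def stepup(level):
        r = 0
        for i in range(1, m + 1):
            if items[i - 1][1] <= i * level / m:
                r = i
        return r

    r1 = stepup(q1)
    if r1 == 0:
        return set()
    if r1 == m:
        return {k for k, _ in items}
    r2 = stepup(q1 * m / (m - r1))
    return {k for k, _ in items[:r2]}


def brute_qvalues(pvals: dict, grid_step: float = 0.001) -> dict:
    """Smallest grid level at which brute_bky rejects each test (1 if never)."""
    out = {k: 1.0 for k in pvals}
    level = grid_step
    while level < 1.0:
        rej = brute_bky(pvals, level)
        for k in rej:
            if out[k] == 1.0:
                out[k] = round(level, 10)
        level = round(level + grid_step, 10)
    return out


def cluster_bootstrap_se(table_df, fit_fn, stat_fn, n_boot: int, seed: int) -> float:
    """SE of a statistic over cluster (female) resamples."""
    rng = np.random.default_rng(seed)
    females = table_df["female_id"].unique()
    groups = {f: table_df[table_df["female_id"] == f] for f in females}
    stats = []
    for _ in range(n_boot):
        draw = rng.choice(females, size=len(females), replace=True)
        parts = []
        for b, f in enumerate(draw):
            part = groups[f].copy()
            part["female_id"] = f"b{b}"  # resampled clusters are distinct
            parts.append(part)
        df = pd.concat(parts, ignore_index=True)
        try:
            stats.append(stat_fn(fit_fn(df)))
        except Exception:
            continue
    return float(np.std(stats, ddof=1))


# ---------------------------------------------------------------------------
# state-walk oracle for the risk-set builders
# ---------------------------------------------------------------------------


def walk_conception_records(states, pregnancies) -> list[tuple]:
    """(female, month, outcome) for every cycling-on-day-1 month, by direct walk."""
    conc = set()
    for row in pregnancies:
        conc.add((row["female_id"], pd.Period(row["conception_date"], freq="M")))
    out = []
    for row in states:
        if row["state"] == "cycling":
            key = (row["female_id"], pd.Period(row["month"], freq="M"))
            out.append((key[0], key[1], int(key in conc)))
    return out


def walk_livebirth_records(pregnancies) -> list[tuple]:
    """(female, conception_date, outcome) for completed pregnancies only."""
    out = []
    for row in pregnancies:
        if row["end_date"] is None or pd.isna(row["end_date"]):
            continue
        out.append((row["female_id"], row["conception_date"], int(bool(row["live"]))))
    return out


def walk_infant_records(infants, mother_deaths, data_end) -> list[tuple]:
    """(mother, infant, outcome) after censoring and maternal-death exclusion."""
    data_end = pd.Timestamp(data_end)
    out = []
    for row in infants:
        birth = pd.Timestamp(row["birth_date"])
        weaning = birth + pd.Timedelta(days=490)
        death = row["death_date"]
        death = pd.Timestamp(death) if death is not None and pd.notna(death) else None
        died_early = death is not None and death < weaning
        if not died_early and data_end < weaning:
            continue  # censored
        anchor = death if died_early else weaning
        mdeath = mother_deaths.get(row["mother_id"])
        if mdeath is not None and pd.Timestamp(mdeath) < anchor:
            continue  # mother died before her infant
        out.append((row["mother_id"], row["infant_id"], int(not died_early)))
    return out
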
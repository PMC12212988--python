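"""Shared fixtures: small rainfall/rank series, toy reproductive histories, panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcar.panel_builder import (
    AnalysisTable,
    RainSeries,
    RankSeries,
    ReproData,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def seeded_rain():
    """Three years of seeded daily rainfall starting 2000-01-01."""
    r = np.random.default_rng(7)
    days = pd.date_range("2000-01-01", periods=3 * 365 + 1, freq="D")
    depths = np.round(r.gamma(1.2, 2.0, size=len(days)) * (r.random(len(days)) < 0.3), 3)
    return RainSeries(pd.Series(depths, index=days))


def make_rain(start, n_days, fn):
    days = pd.date_range(start, periods=n_days, freq="D")
    return RainSeries(pd.Series([float(fn(i, d)) for i, d in enumerate(days)], index=days))


@pytest.fixture
def constant_rain():
    """One mm per day for three full years."""
    return make_rain("2000-01-01", 3 * 365 + 1, lambda i, d: 1.0)


def make_analysis_table(df: pd.DataFrame, outcome_kind="conception",
                        environment_kind="rank") -> AnalysisTable:
    df = df.copy()
    defaults = {
        "group_id": "g0", "month": "m000", "age": 10.0, "group_size": 30.0,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if "age_sq" not in df.columns:
        df["age_sq"] = df["age"] ** 2
    if "delta" not in df.columns:
        df["delta"] = df["e1"] - df["e0"]
    if "abs_delta" not in df.columns:
        df["abs_delta"] = df["delta"].abs()
    return AnalysisTable(df, outcome_kind, environment_kind)


def quadratic_surface(gamma: dict):
    """The generative quadratic surface as a plain function of (e0, abs_delta)."""

    def f(e0, d):
        return (
            gamma.get("intercept", 0.0)
            + gamma.get("e0", 0.0) * e0
            + gamma.get("abs_delta", 0.0) * d
            + gamma.get("e0_sq", 0.0) * e0**2
            + gamma.get("abs_delta_sq", 0.0) * d**2
            + gamma.get("e0_x_abs_delta", 0.0) * e0 * d
        )

    return f


def noiseless_table(gamma: dict, n=60, seed=0, outcome_kind="conception") -> AnalysisTable:
    """Records whose outcome lies exactly on a known quadratic surface (no FE)."""
    r = np.random.default_rng(seed)
    e0 = r.uniform(0, 1, n)
    e1 = np.clip(e0 + r.normal(0, 0.2, n), 0, 1)
    f = quadratic_surface(gamma)
    d = np.abs(e1 - e0)
    df = pd.DataFrame(
        {
            "female_id": [f"f{i % 20:03d}" for i in range(n)],
            "e0": e0, "e1": e1, "outcome": f(e0, d),
            "age": r.uniform(5, 20, n), "group_size": r.uniform(10, 60, n),
        }
    )
    return make_analysis_table(df, outcome_kind=outcome_kind)


def random_history(seed: int, n_females=8, n_months=48):
    """Random but internally consistent reproductive history plus raw event lists.

    Returns (ReproData, RainSeries, RankSeries, states, pregnancies, infants,
    mother_deaths, data_end) where the plain lists/dicts feed the brute-force
    state-walk oracles.
    """
    r = np.random.default_rng(seed)
    start = pd.Timestamp("1990-01-01")
    months = pd.period_range(start, periods=n_months, freq="M")
    data_end = months[-1].end_time.normalize()

    days = pd.date_range(start - pd.DateOffset(years=10), data_end, freq="D")
    rain = RainSeries(pd.Series(
        np.round(r.gamma(1.1, 2.5, len(days)) * (r.random(len(days)) < 0.25), 2),
        index=days,
    ))

    females_rows, states_rows, preg_rows, infant_rows, rank_rows = [], [], [], [], []
    census_rows = [
        {"group_id": g, "month": m, "mean_size": 20.0 + 10.0 * r.random()}
        for g in ("g0", "g1") for m in months
    ]
    mother_deaths = {}
    for j in range(n_females):
        fid = f"F{j:02d}"
        mid = f"M{j:02d}"
        group = "g0" if j % 2 == 0 else "g1"
        birth = start - pd.DateOffset(years=6) + pd.Timedelta(days=int(r.integers(0, 365)))
        death = (
            data_end - pd.Timedelta(days=int(r.integers(0, 500)))
            if r.random() < 0.25 else pd.NaT
        )
        females_rows.append({"female_id": fid, "mother_id": mid, "birth_date": birth,
                             "death_date": death, "group_id": group})
        females_rows.append({"female_id": mid, "mother_id": None, "birth_date": pd.NaT,
                             "death_date": pd.NaT, "group_id": group})
        if pd.notna(death):
            mother_deaths[fid] = death
        # mother rank data around the subject's birth and subject adult ranks
        for m in pd.period_range(birth - pd.DateOffset(months=2),
                                 birth + pd.DateOffset(months=2), freq="M"):
            if r.random() < 0.9:
                rank_rows.append({"female_id": mid, "month": m,
                                  "rank": float(r.uniform(0, 1))})
        for m in months:
            if r.random() < 0.95:
                rank_rows.append({"female_id": fid, "month": m,
                                  "rank": float(r.uniform(0, 1))})

        state = "cycling"
        months_preg = 0
        conception = None
        n_inf = 0
        for m in months:
            if pd.notna(death) and m.start_time > death:
                break
            states_rows.append({"female_id": fid, "month": m, "state": state,
                                "group_id": group})
            if state == "cycling":
                if r.random() < 0.2:
                    conception = m.start_time + pd.Timedelta(days=int(r.integers(0, 27)))
                    state = "pregnant"
                    months_preg = 0
            elif state == "pregnant":
                months_preg += 1
                if months_preg >= 6:
                    end = conception + pd.Timedelta(days=178)
                    live = bool(r.random() < 0.85)
                    preg_rows.append({"female_id": fid,
                                      "conception_date": conception,
                                      "end_date": end, "live": live})
                    if live:
                        n_inf += 1
                        if r.random() < 0.3:
                            idd = end + pd.Timedelta(days=int(r.integers(5, 700)))
                        else:
                            idd = None
                        infant_rows.append({"infant_id": f"{fid}i{n_inf}",
                                            "mother_id": fid,
                                            "birth_date": end, "death_date": idd})
                        state = "postpartum-amenorrhea"
                    else:
                        state = "cycling"
                    conception = None
            else:
                if r.random() < 0.3:
                    state = "cycling"
        if state == "pregnant" and conception is not None:
            preg_rows.append({"female_id": fid, "conception_date": conception,
                              "end_date": None, "live": False})

    females = pd.DataFrame(females_rows).drop_duplicates("female_id")
    states = pd.DataFrame(states_rows)
    pregnancies = pd.DataFrame(preg_rows, columns=["female_id", "conception_date",
                                                   "end_date", "live"])
    pregnancies["end_date"] = pd.to_datetime(pregnancies["end_date"])
    infants = pd.DataFrame(infant_rows, columns=["infant_id", "mother_id",
                                                 "birth_date", "death_date"])
    infants["death_date"] = pd.to_datetime(infants["death_date"])
    census = pd.DataFrame(census_rows)
    data = ReproData(females, states, pregnancies, infants, census)
    ranks = RankSeries(pd.DataFrame(rank_rows, columns=["female_id", "month", "rank"]))
    return (data, rain, ranks, states_rows, preg_rows, infant_rows,
            mother_deaths, data_end)
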
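"""Build conditional risk-set analysis tables from longitudinal fertility records.

Three binary fertility outcomes are analysed, each on its own risk set:

* ``conception`` — one record per female-month in which the female was cycling
  on the first day of the month; outcome 1 iff she conceived that month.
* ``live-birth`` — one record per completed pregnancy; outcome 1 iff it ended
  in a live birth.  In-progress pregnancies are censored and dropped.
* ``infant-survival`` — one record per live birth; outcome 1 iff the infant
  survived to 70 weeks.  Infants not yet 70 weeks old at the end of data
  collection are dropped, as are records where the mother died before her
  infant (early maternal loss strongly predicts infant death).

Each record carries the developmental environment ``e0`` (mean monthly
rainfall in the female's first year of life, or the mother's proportional
dominance rank in the three months around the female's birth), the adult
environment ``e1`` measured on an outcome-specific window, their difference
``delta = e1 - e0`` and its magnitude, plus age, age squared and group size
covariates.

All time windows are half-open ``[start, end)`` on calendar dates; "first
year of life" means ``[birth, birth + 12 calendar months)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DataIntegrityError,
    MissingDataError,
)

ENV_KINDS = ("rank", "rain")
OUTCOME_KINDS = ("conception", "live-birth", "infant-survival")
STATES = ("cycling", "pregnant", "postpartum-amenorrhea")

#: 70 weeks, the average age at weaning, in days.
WEANING_DAYS = 70 * 7

#: Fixed column order of an analysis record.
RECORD_COLUMNS = (
    "female_id",
    "group_id",
    "month",
    "outcome",
    "e0",
    "e1",
    "delta",
    "abs_delta",
    "age",
    "age_sq",
    "group_size",
)

DROP_COLUMNS = ("table", "reason", "female_id", "key")


# ---------------------------------------------------------------------------
# environment series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RainSeries:
    """Daily rainfall series (mm/day) indexed by calendar date.

    Dates must be strictly increasing and depths non-negative.  Days may be
    missing; window operations treat missing days as a coverage error unless
    explicitly configured otherwise.
    """

    values: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("RainSeries index must be a DatetimeIndex")
        if len(idx) and not idx.is_monotonic_increasing:
            raise ValueError("rainfall dates must be strictly increasing")
        if idx.has_duplicates:
            raise ValueError("duplicate rainfall dates")
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any():
            raise ValueError("rainfall depths must be non-negative and non-missing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RainSeries":
        s = pd.Series(
            df["rain_mm"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(pd.to_datetime(df["date"])),
        ).sort_index()
        return cls(s)

    @property
    def start(self) -> pd.Timestamp:
        return self.values.index[0]

    @property
    def end(self) -> pd.Timestamp:
        """First day *after* coverage ends."""
        return self.values.index[-1] + pd.Timedelta(days=1)


def mean_monthly_rain(
    series: RainSeries,
    window_start,
    months: int,
    *,
    missing_as_zero: bool = False,
) -> float:
    """Average monthly rainfall over ``[window_start, window_start + months)``.

    The total daily rainfall over the half-open calendar window is divided by
    the number of window months — never by days/30 — so a window spanning a
    leap day is still divided by ``months``.

    Raises :class:`CoverageError` if any day of the window is absent from the
    series, unless ``missing_as_zero`` is set.
    """
    start = pd.Timestamp(window_start)
    end = start + pd.DateOffset(months=months)
    sub = series.values.loc[(series.values.index >= start) & (series.values.index < end)]
    n_expected = (end - start).days
    if len(sub) < n_expected and not missing_as_zero:
        covered = set(sub.index)
        gap = next(
            d for d in pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
            if d not in covered
        )
        raise CoverageError(
            f"rainfall window [{start.date()}, {end.date()}) has "
            f"{n_expected - len(sub)} missing day(s), first gap at {gap.date()}"
        )
    return float(sub.sum()) / months


def rain_development(series: RainSeries, birth) -> float:
    """Mean monthly rainfall over the subject's first 12 months of life."""
    return mean_monthly_rain(series, birth, 12)


def rain_adult(series: RainSeries, event) -> float:
    """Mean monthly rainfall over the 12 months ending at the event anchor.

    The anchor is the first day of the cycling month (conception models), the
    pregnancy end date (live-birth models), or the infant death / 70-week
    date (infant-survival models).
    """
    anchor = pd.Timestamp(event)
    return mean_monthly_rain(series, anchor - pd.DateOffset(months=12), 12)


@dataclass(frozen=True)
class RankSeries:
    """Monthly proportional dominance ranks, one value per female-month.

    Rank is the proportion of adult female groupmates the subject outranks,
    in [0, 1].  Months may have gaps; window means are gap-tolerant.
    """

    values: pd.DataFrame  # columns: female_id, month (Period[M]), rank

    def __post_init__(self) -> None:
        df = self.values
        r = df["rank"].to_numpy(dtype=float)
        if np.isnan(r).any() or (r < 0).any() or (r > 1).any():
            raise ValueError("ranks must lie in [0, 1]")
        if df.duplicated(["female_id", "month"]).any():
            raise ValueError("duplicate female-month rank entries")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RankSeries":
        out = df.copy()
        out["month"] = pd.PeriodIndex(out["month"], freq="M")
        return cls(out[["female_id", "month", "rank"]])

    def lookup(self) -> dict:
        """Dict ``(female_id, Period) -> rank`` for fast window means."""
        return {
            (f, m): r
            for f, m, r in zip(
                self.values["female_id"], self.values["month"], self.values["rank"]
            )
        }


def months_around(month, before: int = 1, after: int = 1) -> list[pd.Period]:
    """The window {month - before, ..., month, ..., month + after}."""
    m = pd.Period(month, freq="M")
    return [m + k for k in range(-before, after + 1)]


def month_span(first, last) -> list[pd.Period]:
    """Inclusive list of calendar months from ``first`` to ``last``."""
    a, b = pd.Period(first, freq="M"), pd.Period(last, freq="M")
    return [a + k for k in range((b - a).n + 1)]


def rank_window_mean(series: RankSeries, female, months: Iterable) -> float:
    """Gap-tolerant mean of the female's available monthly ranks in a window.

    Raises :class:`MissingDataError` when no month in the window has data;
    callers exclude such records upstream (with a logged drop reason).
    """
    table = series.lookup() if isinstance(series, RankSeries) else series
    vals = [
        table[(female, pd.Period(m, freq="M"))]
        for m in months
        if (female, pd.Period(m, freq="M")) in table
    ]
    if not vals:
        raise MissingDataError(f"no rank data for {female!r} in window {list(months)}")
    return float(np.mean(vals))


def compute_delta(e0: float, e1: float, kind_e0: str | None = None,
                  kind_e1: str | None = None) -> tuple[float, float]:
    """Environment difference ``delta = e1 - e0`` and its magnitude.

    Optional kind tags guard against pairing a rank value with a rainfall
    value: a mismatch raises ``TypeError``.
    """
    if kind_e0 is not None and kind_e1 is not None and kind_e0 != kind_e1:
        raise TypeError(f"environment kinds differ: {kind_e0!r} vs {kind_e1!r}")
    delta = e1 - e0
    return delta, abs(delta)


# ---------------------------------------------------------------------------
# raw longitudinal records
# ---------------------------------------------------------------------------


@dataclass
class ReproData:
    """Tidy longitudinal reproductive records for a set of females.

    ``females``: female_id, mother_id, birth_date, death_date (NaT if alive),
    group_id.  ``states``: female_id, month (Period[M]), state (the
    reproductive state on the first day of the month), group_id.
    ``pregnancies``: female_id, conception_date, end_date (NaT while in
    progress), live (bool).  ``infants``: infant_id, mother_id, birth_date,
    death_date (NaT if alive).  ``census``: group_id, month (Period[M]),
    mean_size (mean individuals per day).
    """

    females: pd.DataFrame
    states: pd.DataFrame
    pregnancies: pd.DataFrame
    infants: pd.DataFrame
    census: pd.DataFrame

    def validate(self) -> None:
        """Raise :class:`DataIntegrityError` on internally inconsistent records."""
        preg = self.pregnancies
        if preg["conception_date"].isna().any():
            bad = preg.loc[preg["conception_date"].isna(), "female_id"].tolist()
            raise DataIntegrityError(f"pregnancy without conception date: {bad}")
        ended = preg.dropna(subset=["end_date"])
        if (pd.to_datetime(ended["end_date"]) <= pd.to_datetime(ended["conception_date"])).any():
            raise DataIntegrityError("pregnancy end date not after conception date")
        inf = self.infants.dropna(subset=["death_date"])
        if (pd.to_datetime(inf["death_date"]) < pd.to_datetime(inf["birth_date"])).any():
            raise DataIntegrityError("infant death date before birth date")
        bad_state = set(self.states["state"]) - set(STATES)
        if bad_state:
            raise DataIntegrityError(f"unknown reproductive states: {sorted(bad_state)}")

    def data_end(self) -> pd.Timestamp:
        """Last observed day (end of the final state month)."""
        last = self.states["month"].max()
        return last.end_time.normalize()


# ---------------------------------------------------------------------------
# analysis tables
# ---------------------------------------------------------------------------


@dataclass
class AnalysisTable:
    """Risk-set observations for one outcome under one environment variable."""

    df: pd.DataFrame
    outcome_kind: str
    environment_kind: str

    def __post_init__(self) -> None:
        if self.outcome_kind not in OUTCOME_KINDS:
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")
        if self.environment_kind not in ENV_KINDS:
            raise ValueError(f"unknown environment kind {self.environment_kind!r}")
        missing = [c for c in RECORD_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"analysis table missing columns {missing}")
        self.df = self.df.loc[:, list(RECORD_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class _Collector:
    """Accumulates kept records and reasoned drops during a build."""

    table: str
    rows: list = field(default_factory=list)
    drops: list = field(default_factory=list)

    def keep(self, **row) -> None:
        self.rows.append(row)

    def drop(self, reason: str, female_id, key) -> None:
        self.drops.append(
            {"table": self.table, "reason": reason, "female_id": female_id, "key": str(key)}
        )

    def finish(self, outcome_kind: str, environment_kind: str):
        df = pd.DataFrame(self.rows, columns=list(RECORD_COLUMNS))
        drops = pd.DataFrame(self.drops, columns=list(DROP_COLUMNS))
        return AnalysisTable(df, outcome_kind, environment_kind), drops


class _EnvHelper:
    """Caches per-female development environments and census lookups."""

    def __init__(self, data: ReproData, environment: str,
                 rain: RainSeries | None, ranks: RankSeries | None):
        if environment not in ENV_KINDS:
            raise ValueError(f"unknown environment {environment!r}")
        if environment == "rain" and rain is None:
            raise ValueError("rain environment requested without a rain series")
        if environment == "rank" and ranks is None:
            raise ValueError("rank environment requested without a rank series")
        self.environment = environment
        self.rain = rain
        self.rank_lookup = ranks.lookup() if ranks is not None else {}
        self.females = data.females.set_index("female_id")
        self.census = {
            (g, m): s
            for g, m, s in zip(
                data.census["group_id"], data.census["month"], data.census["mean_size"]
            )
        }
        self._e0_cache: dict = {}

    def birth(self, female) -> pd.Timestamp:
        return pd.Timestamp(self.females.at[female, "birth_date"])

    def e0(self, female) -> float:
        """Developmental environment; raises Coverage/MissingData errors."""
        if female in self._e0_cache:
            val = self._e0_cache[female]
            if isinstance(val, Exception):
                raise val
            return val
        try:
            if self.environment == "rain":
                val = rain_development(self.rain, self.birth(female))
            else:
                mother = self.females.at[female, "mother_id"]
                if mother is None or (isinstance(mother, float) and math.isnan(mother)):
                    raise MissingDataError(f"no mother recorded for {female!r}")
                birth_month = pd.Period(self.birth(female), freq="M")
                val = rank_window_mean(self.rank_lookup, mother, months_around(birth_month))
        except (CoverageError, MissingDataError) as exc:
            self._e0_cache[female] = exc
            raise
        self._e0_cache[female] = val
        return val

    def e1_rank(self, female, months) -> float:
        return rank_window_mean(self.rank_lookup, female, months)

    def e1_rain(self, anchor) -> float:
        return rain_adult(self.rain, anchor)

    def group_size(self, group, months) -> float:
        """Mean of monthly mean daily census over the span; NaN if no data."""
        vals = [self.census[(group, m)] for m in months if (group, m) in self.census]
        return float(np.mean(vals)) if vals else float("nan")


def _age_years(birth: pd.Timestamp, at: pd.Timestamp) -> float:
    return (pd.Timestamp(at) - pd.Timestamp(birth)).days / 365.25


def build_conception_table(
    data: ReproData,
    environment: str,
    rain: RainSeries | None = None,
    ranks: RankSeries | None = None,
) -> tuple[AnalysisTable, pd.DataFrame]:
    """One record per female-month cycling on day 1; outcome 1 iff she conceived.

    Months in which the female was pregnant or in postpartum amenorrhea on the
    first day are excluded from the risk set.  Records with unobtainable
    environment values or covariates are dropped with a reasoned log entry.
    """
    data.validate()
    env = _EnvHelper(data, environment, rain, ranks)
    conceived = {
        (f, pd.Period(pd.Timestamp(c), freq="M"))
        for f, c in zip(data.pregnancies["female_id"], data.pregnancies["conception_date"])
    }
    out = _Collector("conception")
    cycling = data.states[data.states["state"] == "cycling"]
    for female, month, group in zip(
        cycling["female_id"], cycling["month"], cycling["group_id"]
    ):
        try:
            e0 = env.e0(female)
        except (CoverageError, MissingDataError):
            out.drop("missing-development-environment", female, month)
            continue
        try:
            if environment == "rank":
                e1 = env.e1_rank(female, months_around(month))
            else:
                e1 = env.e1_rain(month.start_time)
        except (CoverageError, MissingDataError):
            out.drop("missing-adult-environment", female, month)
            continue
        gsize = env.group_size(group, [month])
        if math.isnan(gsize):
            out.drop("missing-covariate", female, month)
            continue
        delta, abs_delta = compute_delta(e0, e1)
        age = _age_years(env.birth(female), month.start_time)
        out.keep(
            female_id=female, group_id=group, month=str(month),
            outcome=int((female, month) in conceived),
            e0=e0, e1=e1, delta=delta, abs_delta=abs_delta,
            age=age, age_sq=age * age, group_size=gsize,
        )
    return out.finish("conception", environment)


def _female_group(data: ReproData, female, month) -> object:
    """Group membership for a female-month, falling back to the static group."""
    sub = data.states[
        (data.states["female_id"] == female) & (data.states["month"] == month)
    ]
    if len(sub):
        return sub["group_id"].iloc[0]
    row = data.females.loc[data.females["female_id"] == female]
    return row["group_id"].iloc[0] if len(row) else None


def build_livebirth_table(
    data: ReproData,
    environment: str,
    rain: RainSeries | None = None,
    ranks: RankSeries | None = None,
) -> tuple[AnalysisTable, pd.DataFrame]:
    """One record per completed pregnancy; outcome 1 iff it ended in a live birth.

    Pregnancies still in progress at the end of data collection are censored
    and dropped.  A pregnancy without a conception date is a data-integrity
    error.
    """
    data.validate()
    env = _EnvHelper(data, environment, rain, ranks)
    out = _Collector("live-birth")
    for row in data.pregnancies.itertuples(index=False):
        female = row.female_id
        key = pd.Timestamp(row.conception_date).date()
        if pd.isna(row.end_date):
            out.drop("censored-pregnancy", female, key)
            continue
        end = pd.Timestamp(row.end_date)
        end_month = pd.Period(end, freq="M")
        span = month_span(pd.Period(pd.Timestamp(row.conception_date), freq="M"), end_month)
        try:
            e0 = env.e0(female)
        except (CoverageError, MissingDataError):
            out.drop("missing-development-environment", female, key)
            continue
        try:
            if environment == "rank":
                e1 = env.e1_rank(female, span)
            else:
                e1 = env.e1_rain(end)
        except (CoverageError, MissingDataError):
            out.drop("missing-adult-environment", female, key)
            continue
        group = _female_group(data, female, end_month)
        gsize = env.group_size(group, span)
        if group is None or math.isnan(gsize):
            out.drop("missing-covariate", female, key)
            continue
        delta, abs_delta = compute_delta(e0, e1)
        age = _age_years(env.birth(female), end)
        out.keep(
            female_id=female, group_id=group, month=str(end_month),
            outcome=int(bool(row.live)),
            e0=e0, e1=e1, delta=delta, abs_delta=abs_delta,
            age=age, age_sq=age * age, group_size=gsize,
        )
    return out.finish("live-birth", environment)


def build_infantsurvival_table(
    data: ReproData,
    environment: str,
    rain: RainSeries | None = None,
    ranks: RankSeries | None = None,
    data_end=None,
) -> tuple[AnalysisTable, pd.DataFrame]:
    """One record per live birth; outcome 1 iff the infant survived to 70 weeks.

    Infants not yet 70 weeks old at ``data_end`` are censored and dropped.
    Records where the mother died before her infant (before the infant's
    death, or before the infant reached 70 weeks) are excluded.
    """
    data.validate()
    env = _EnvHelper(data, environment, rain, ranks)
    end_of_data = pd.Timestamp(data_end) if data_end is not None else data.data_end()
    out = _Collector("infant-survival")
    mothers = data.females.set_index("female_id")
    for row in data.infants.itertuples(index=False):
        mother = row.mother_id
        birth = pd.Timestamp(row.birth_date)
        key = row.infant_id
        weaning = birth + pd.Timedelta(days=WEANING_DAYS)
        death = pd.Timestamp(row.death_date) if pd.notna(row.death_date) else None
        died_early = death is not None and death < weaning
        if not died_early and end_of_data < weaning:
            out.drop("censored-infant", mother, key)
            continue
        anchor = death if died_early else weaning
        mother_death = mothers.at[mother, "death_date"] if mother in mothers.index else pd.NaT
        if pd.notna(mother_death) and pd.Timestamp(mother_death) < anchor:
            out.drop("maternal-death", mother, key)
            continue
        anchor_month = pd.Period(anchor, freq="M")
        span = month_span(pd.Period(birth, freq="M"), anchor_month)
        try:
            e0 = env.e0(mother)
        except (CoverageError, MissingDataError):
            out.drop("missing-development-environment", mother, key)
            continue
        try:
            if environment == "rank":
                # monthly mean over the 12 months preceding the anchor month
                window = [anchor_month - k for k in range(12, 0, -1)]
                e1 = env.e1_rank(mother, window)
            else:
                e1 = env.e1_rain(anchor)
        except (CoverageError, MissingDataError):
            out.drop("missing-adult-environment", mother, key)
            continue
        group = _female_group(data, mother, pd.Period(birth, freq="M"))
        gsize = env.group_size(group, span)
        if group is None or math.isnan(gsize):
            out.drop("missing-covariate", mother, key)
            continue
        delta, abs_delta = compute_delta(e0, e1)
        age = _age_years(env.birth(mother), birth)
        out.keep(
            female_id=mother, group_id=group, month=str(pd.Period(birth, freq="M")),
            outcome=int(not died_early),
            e0=e0, e1=e1, delta=delta, abs_delta=abs_delta,
            age=age, age_sq=age * age, group_size=gsize,
        )
    return out.finish("infant-survival", environment)


_BUILDERS = {
    "conception": build_conception_table,
    "live-birth": build_livebirth_table,
    "infant-survival": build_infantsurvival_table,
}


def build_table(outcome_kind: str, data: ReproData, environment: str,
                rain: RainSeries | None = None, ranks: RankSeries | None = None,
                **kwargs) -> tuple[AnalysisTable, pd.DataFrame]:
    """Dispatch to the risk-set builder for ``outcome_kind``."""
    try:
        builder = _BUILDERS[outcome_kind]
    except KeyError:
        raise ValueError(f"unknown outcome kind {outcome_kind!r}") from None
    return builder(data, environment, rain=rain, ranks=ranks, **kwargs)
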
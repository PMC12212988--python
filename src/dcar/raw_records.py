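"""Generate raw longitudinal records with the structure the panel builder consumes.

Produces the four input tables — a daily rainfall series, monthly proportional
dominance ranks, reproductive event records and monthly group census — by
running a monthly reproductive state machine for a cohort of females:

* a cycling female conceives with a fixed monthly probability;
* pregnancy lasts six months and ends in a live birth with high probability;
* a live birth starts an infant whose monthly death hazard is calibrated so
  roughly three quarters survive to 70 weeks, and a postpartum-amenorrhea
  spell that ends after weaning (or early, if the infant dies);
* subjects hold a dominance rank near their mother's, evolving as a bounded
  random walk with occasional missing months.

Mothers of the study subjects are "pre-study" females that contribute rank
data only, so every subject has an observable developmental environment.
The generator is demographic scaffolding for end-to-end runs: deltas emerge
mechanically from rainfall seasonality and rank drift, with no built-in
effect of either on fertility (the null world).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_builder import RainSeries, RankSeries, ReproData

PREGNANCY_MONTHS = 6
CONCEPTION_PROB = 0.13
LIVE_BIRTH_PROB = 0.92
INFANT_MONTHLY_HAZARD = 0.019  # ~73% survival over the 16.3-month weaning span
SUBJECT_MONTHLY_HAZARD = 0.003
RESUME_CYCLING_PROB = 0.35  # after weaning or infant death
RANK_WALK_SD = 0.02
RANK_MISSING_PROB = 0.02


@dataclass(frozen=True)
class RawDataConfig:
    n_subjects: int = 60
    n_mothers: int = 25
    n_groups: int = 3
    start: str = "1980-01-01"
    years: int = 26
    maturity_years: int = 5
    seed: int = 0


@dataclass
class RawTables:
    """The four delimited input tables plus their typed wrappers."""

    rain: pd.DataFrame
    ranks: pd.DataFrame
    females: pd.DataFrame
    states: pd.DataFrame
    pregnancies: pd.DataFrame
    infants: pd.DataFrame
    census: pd.DataFrame

    def rain_series(self) -> RainSeries:
        return RainSeries.from_frame(self.rain)

    def rank_series(self) -> RankSeries:
        return RankSeries.from_frame(self.ranks)

    def repro_data(self) -> ReproData:
        females = self.females.copy()
        females["birth_date"] = pd.to_datetime(females["birth_date"])
        females["death_date"] = pd.to_datetime(females["death_date"])
        states = self.states.copy()
        states["month"] = pd.PeriodIndex(states["month"], freq="M")
        preg = self.pregnancies.copy()
        preg["conception_date"] = pd.to_datetime(preg["conception_date"])
        preg["end_date"] = pd.to_datetime(preg["end_date"])
        infants = self.infants.copy()
        infants["birth_date"] = pd.to_datetime(infants["birth_date"])
        infants["death_date"] = pd.to_datetime(infants["death_date"])
        census = self.census.copy()
        census["month"] = pd.PeriodIndex(census["month"], freq="M")
        return ReproData(females, states, preg, infants, census)


def _daily_rain(rng, start: pd.Timestamp, years: int) -> pd.DataFrame:
    """Seasonal wet-day/gamma daily rainfall, ~29 mm per month on average."""
    days = pd.date_range(start, periods=365 * years + years // 4, freq="D")
    doy = days.dayofyear.to_numpy()
    season = 1.0 + 0.9 * np.sin(2.0 * np.pi * (doy - 80) / 365.25)
    wet = rng.random(len(days)) < 0.22 * season
    depth = rng.gamma(shape=1.3, scale=3.5, size=len(days)) * season
    return pd.DataFrame({"date": days.strftime("%Y-%m-%d"), "rain_mm": np.round(wet * depth, 2)})


def _rank_walk(rng, start_rank: float, months: pd.PeriodIndex) -> dict:
    out = {}
    r = float(np.clip(start_rank, 0.02, 0.98))
    for m in months:
        r = float(np.clip(r + rng.normal(0.0, RANK_WALK_SD), 0.0, 1.0))
        if rng.random() >= RANK_MISSING_PROB:
            out[m] = round(r, 4)
    return out


def simulate_raw_records(config: RawDataConfig | None = None) -> RawTables:
    """Run the cohort state machine and emit the four raw tables."""
    config = config or RawDataConfig()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start)
    end = start + pd.DateOffset(years=config.years)
    all_months = pd.period_range(start, end - pd.Timedelta(days=1), freq="M")

    rain = _daily_rain(rng, start, config.years)

    females_rows = []
    ranks_rows = []
    states_rows = []
    preg_rows = []
    infant_rows = []

    # pre-study mothers: rank data from the start, no reproductive records
    mother_ids = [f"M{j:03d}" for j in range(config.n_mothers)]
    mother_group = {m: f"g{rng.integers(config.n_groups)}" for m in mother_ids}
    mother_rank = {}
    for m in mother_ids:
        walk = _rank_walk(rng, rng.uniform(0.05, 0.95), all_months)
        mother_rank[m] = walk
        ranks_rows += [{"female_id": m, "month": str(k), "rank": v} for k, v in walk.items()]
        females_rows.append(
            {"female_id": m, "mother_id": None, "birth_date": None,
             "death_date": None, "group_id": mother_group[m]}
        )

    # subjects: born in the first years, observed as adults from maturity
    subject_ids = [f"F{j:03d}" for j in range(config.n_subjects)]
    for sid in subject_ids:
        mother = mother_ids[int(rng.integers(config.n_mothers))]
        birth = start + pd.Timedelta(days=int(rng.integers(400, 365 * 8)))
        group = mother_group[mother]
        adult_from = pd.Period(birth + pd.DateOffset(years=config.maturity_years), freq="M")
        adult_months = pd.period_range(adult_from, all_months[-1], freq="M")
        if len(adult_months) == 0:
            continue
        mother_birth_rank = mother_rank[mother].get(pd.Period(birth, freq="M"), 0.5)
        walk = _rank_walk(rng, mother_birth_rank + rng.normal(0.0, 0.1), adult_months)
        ranks_rows += [{"female_id": sid, "month": str(k), "rank": v} for k, v in walk.items()]

        death = pd.NaT
        state = "cycling"
        months_pregnant = 0
        conception = None
        infant_death_month = None
        weaning_month = None
        n_inf = 0
        for m in adult_months:
            states_rows.append(
                {"female_id": sid, "month": str(m), "state": state, "group_id": group}
            )
            month_start = m.start_time
            if rng.random() < SUBJECT_MONTHLY_HAZARD:
                death = month_start + pd.Timedelta(days=int(rng.integers(0, 28)))
                break
            if state == "cycling":
                if rng.random() < CONCEPTION_PROB:
                    conception = month_start + pd.Timedelta(days=int(rng.integers(0, 28)))
                    state = "pregnant"
                    months_pregnant = 0
            elif state == "pregnant":
                months_pregnant += 1
                if months_pregnant >= PREGNANCY_MONTHS:
                    end_date = conception + pd.Timedelta(days=int(rng.integers(170, 185)))
                    live = bool(rng.random() < LIVE_BIRTH_PROB)
                    preg_rows.append(
                        {"female_id": sid, "conception_date": str(conception.date()),
                         "end_date": str(end_date.date()), "live": live}
                    )
                    if live:
                        n_inf += 1
                        iid = f"{sid}i{n_inf}"
                        surv_months = rng.geometric(INFANT_MONTHLY_HAZARD)
                        if surv_months <= 17:
                            idd = end_date + pd.Timedelta(days=int(30.4 * surv_months))
                            infant_death_month = pd.Period(idd, freq="M")
                        else:
                            idd = pd.NaT
                            infant_death_month = None
                        infant_rows.append(
                            {"infant_id": iid, "mother_id": sid,
                             "birth_date": str(end_date.date()),
                             "death_date": str(idd.date()) if pd.notna(idd) else None}
                        )
                        weaning_month = pd.Period(
                            end_date + pd.Timedelta(days=70 * 7), freq="M"
                        )
                        state = "postpartum-amenorrhea"
                    else:
                        state = "cycling"
                    conception = None
            else:  # postpartum amenorrhea
                over = (infant_death_month is not None and m >= infant_death_month) or (
                    weaning_month is not None and m >= weaning_month
                )
                if over and rng.random() < RESUME_CYCLING_PROB:
                    state = "cycling"
        # a pregnancy still open at the end of observation stays in progress
        if state == "pregnant" and conception is not None:
            preg_rows.append(
                {"female_id": sid, "conception_date": str(conception.date()),
                 "end_date": None, "live": False}
            )
        females_rows.append(
            {"female_id": sid, "mother_id": mother, "birth_date": str(birth.date()),
             "death_date": str(death.date()) if pd.notna(death) else None,
             "group_id": group}
        )

    census_rows = []
    for g in range(config.n_groups):
        size = rng.uniform(25.0, 45.0)
        for m in all_months:
            size = float(np.clip(size + rng.normal(0.0, 1.0), 12.0, 80.0))
            census_rows.append(
                {"group_id": f"g{g}", "month": str(m), "mean_size": round(size, 2)}
            )

    return RawTables(
        rain=rain,
        ranks=pd.DataFrame(ranks_rows, columns=["female_id", "month", "rank"]),
        females=pd.DataFrame(
            females_rows,
            columns=["female_id", "mother_id", "birth_date", "death_date", "group_id"],
        ),
        states=pd.DataFrame(
            states_rows, columns=["female_id", "month", "state", "group_id"]
        ),
        pregnancies=pd.DataFrame(
            preg_rows, columns=["female_id", "conception_date", "end_date", "live"]
        ),
        infants=pd.DataFrame(
            infant_rows, columns=["infant_id", "mother_id", "birth_date", "death_date"]
        ),
        census=pd.DataFrame(census_rows, columns=["group_id", "month", "mean_size"]),
    )
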
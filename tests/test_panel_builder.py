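"""Risk-set construction, environment windows and delta arithmetic."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_rain, random_history
from oracles import (
    brute_rain_mean,
    walk_conception_records,
    walk_infant_records,
    walk_livebirth_records,
)

from dcar.errors import CoverageError, DataIntegrityError, MissingDataError
from dcar.panel_builder import (
    RainSeries,
    RankSeries,
    ReproData,
    build_conception_table,
    build_infantsurvival_table,
    build_livebirth_table,
    compute_delta,
    mean_monthly_rain,
    months_around,
    rain_adult,
    rain_development,
    rank_window_mean,
)


class TestRainWindows:
    def test_constant_series_full_year(self, constant_rain):
        # 365 days of 1 mm/day averaged over 12 calendar months
        got = mean_monthly_rain(constant_rain, "2000-01-01", 12)
        assert got == pytest.approx(366 / 12)  # 2000 is a leap year
        got = mean_monthly_rain(constant_rain, "2001-01-01", 12)
        assert got == pytest.approx(365 / 12)

    def test_zero_series(self):
        series = make_rain("2000-01-01", 400, lambda i, d: 0.0)
        assert mean_monthly_rain(series, "2000-01-15", 12) == 0.0

    def test_single_wet_month(self):
        series = make_rain("2000-01-01", 400, lambda i, d: 4.0 if i < 30 else 0.0)
        assert rain_development(series, "2000-01-01") == pytest.approx(120 / 12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_daily_sum_oracle(self, seed, seeded_rain):
        r = np.random.default_rng(seed)
        start = pd.Timestamp("2000-01-01") + pd.Timedelta(days=int(r.integers(0, 300)))
        got = mean_monthly_rain(seeded_rain, start, 12)
        want = brute_rain_mean(seeded_rain.values.index, seeded_rain.values.to_numpy(),
                               start, 12)
        assert got == pytest.approx(want, abs=1e-12)
        # the development and adult views are the same windowed mean
        assert rain_development(seeded_rain, start) == pytest.approx(got, abs=1e-12)
        assert rain_adult(seeded_rain, start + pd.DateOffset(months=12)) == pytest.approx(
            got, abs=1e-12
        )

    def test_periodic_series_shift_invariance(self):
        # rainfall repeating every 12 months: shifting the anchor a year changes nothing
        days = pd.date_range("2000-01-01", periods=4 * 366, freq="D")
        depths = [1.0 + np.sin(2 * np.pi * (d.month - 1) / 12) for d in days]
        series = RainSeries(pd.Series(depths, index=days))
        a = rain_adult(series, "2002-03-01")
        b = rain_adult(series, "2003-03-01")
        assert a == pytest.approx(b, rel=2e-2)  # calendar-length wobble only

    def test_coverage_error_identifies_gap(self, constant_rain):
        with pytest.raises(CoverageError, match="missing day"):
            mean_monthly_rain(constant_rain, "1999-06-01", 12)
        # missing days can be configured to count as zero
        got = mean_monthly_rain(constant_rain, "1999-06-01", 12, missing_as_zero=True)
        assert 0 < got < 366 / 12

    def test_rejects_negative_rain(self):
        days = pd.date_range("2000-01-01", periods=3, freq="D")
        with pytest.raises(ValueError):
            RainSeries(pd.Series([1.0, -0.5, 0.0], index=days))


class TestRankWindows:
    @staticmethod
    def series(entries):
        return RankSeries(pd.DataFrame(
            [{"female_id": f, "month": pd.Period(m, freq="M"), "rank": r}
             for f, m, r in entries]
        ))

    def test_symmetric_mean(self):
        s = self.series([("a", "2000-01", 0.4), ("a", "2000-02", 0.5), ("a", "2000-03", 0.6)])
        got = rank_window_mean(s, "a", months_around("2000-02"))
        assert got == pytest.approx(0.5)

    def test_gap_tolerant(self):
        s = self.series([("a", "2000-01", 0.9), ("a", "2000-03", 0.9)])
        assert rank_window_mean(s, "a", months_around("2000-02")) == pytest.approx(0.9)

    def test_empty_window_raises(self):
        s = self.series([("a", "2000-01", 0.9)])
        with pytest.raises(MissingDataError):
            rank_window_mean(s, "a", months_around("2005-06"))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_elementwise_mean_oracle(self, seed):
        r = np.random.default_rng(seed)
        months = pd.period_range("2000-01", periods=12, freq="M")
        keep = r.random(12) < 0.8
        vals = r.uniform(0, 1, 12)
        s = self.series([("a", str(m), v) for m, v, k in zip(months, vals, keep) if k])
        if not keep.any():
            return
        got = rank_window_mean(s, "a", months)
        assert got == pytest.approx(float(np.mean(vals[keep])), abs=1e-12)

    def test_rejects_out_of_range_rank(self):
        with pytest.raises(ValueError):
            self.series([("a", "2000-01", 1.2)])


class TestComputeDelta:
    @pytest.mark.parametrize(
        "e0,e1,delta,absd",
        [(0.5, 0.5, 0.0, 0.0), (0.2, 0.7, 0.5, 0.5), (0.7, 0.2, -0.5, 0.5)],
    )
    def test_values(self, e0, e1, delta, absd):
        got_d, got_a = compute_delta(e0, e1)
        assert got_d == pytest.approx(delta, abs=1e-15)
        assert got_a == pytest.approx(absd, abs=1e-15)
        assert got_a == abs(got_d)  # magnitude identity is bit-exact

    def test_unit_mismatch(self):
        with pytest.raises(TypeError):
            compute_delta(0.5, 30.0, kind_e0="rank", kind_e1="rain")


class TestBuilders:
    def test_conception_risk_set_rules(self):
        """Cycling-on-day-1 months enter; pregnant/amenorrhea months do not."""
        data, rain, ranks, *_ = random_history(seed=11)
        table, drops = build_conception_table(data, "rank", rain=rain, ranks=ranks)
        cyc = data.states[data.states["state"] == "cycling"]
        kept_keys = set(zip(table.df["female_id"], table.df["month"]))
        cyc_keys = {(f, str(m)) for f, m in zip(cyc["female_id"], cyc["month"])}
        assert kept_keys <= cyc_keys
        assert len(table) + len(drops) == len(cyc)
        non_cyc = data.states[data.states["state"] != "cycling"]
        bad = {(f, str(m)) for f, m in zip(non_cyc["female_id"], non_cyc["month"])}
        assert not (kept_keys & bad)
        # no female-month appears twice
        assert len(kept_keys) == len(table)

    @pytest.mark.parametrize("seed", [1, 5, 9, 23])
    def test_conception_outcomes_match_state_walk(self, seed):
        data, rain, ranks, states, pregs, *_ = random_history(seed=seed)
        table, drops = build_conception_table(data, "rank", rain=rain, ranks=ranks)
        oracle = {
            (f, str(m)): y for f, m, y in walk_conception_records(
                [{"female_id": s["female_id"], "month": s["month"], "state": s["state"]}
                 for s in states],
                [{"female_id": p["female_id"], "conception_date": p["conception_date"]}
                 for p in pregs],
            )
        }
        for rec in table.df.itertuples():
            assert oracle[(rec.female_id, rec.month)] == rec.outcome
        assert table.df["outcome"].sum() <= len(pregs)

    def test_livebirth_censoring_and_outcomes(self):
        data, rain, ranks, states, pregs, *_ = random_history(seed=3)
        table, drops = build_livebirth_table(data, "rank", rain=rain, ranks=ranks)
        oracle = walk_livebirth_records(pregs)
        n_in_progress = sum(1 for p in pregs if p["end_date"] is None)
        assert (drops["reason"] == "censored-pregnancy").sum() == n_in_progress
        assert len(table) + len(drops) == len(pregs)
        want = {(f, pd.Timestamp(c)): y for f, c, y in oracle}
        got_ones = int(table.df["outcome"].sum())
        assert got_ones <= sum(y for *_, y in oracle)

    def test_livebirth_missing_conception_is_integrity_error(self):
        data, rain, ranks, *_ = random_history(seed=3)
        data.pregnancies.loc[0, "conception_date"] = pd.NaT
        with pytest.raises(DataIntegrityError):
            build_livebirth_table(data, "rank", rain=rain, ranks=ranks)

    @pytest.mark.parametrize("seed", [2, 7, 13])
    def test_infant_survival_matches_enumeration(self, seed):
        data, rain, ranks, states, pregs, infants, mother_deaths, data_end = (
            random_history(seed=seed)
        )
        table, drops = build_infantsurvival_table(
            data, "rank", rain=rain, ranks=ranks, data_end=data_end
        )
        oracle = walk_infant_records(
            [{"infant_id": i["infant_id"], "mother_id": i["mother_id"],
              "birth_date": i["birth_date"], "death_date": i["death_date"]}
             for i in infants],
            mother_deaths, data_end,
        )
        want = {iid: (m, y) for m, iid, y in oracle}
        dropped_reasons = dict(zip(drops["key"], drops["reason"]))
        env_drop = {"missing-development-environment", "missing-adult-environment",
                    "missing-covariate"}
        # oracle-excluded infants never survive to the table, and the builder
        # logs the same censor/maternal-death reasons the oracle applied
        for i in infants:
            iid = i["infant_id"]
            if iid not in want:
                assert dropped_reasons[iid] in {"censored-infant", "maternal-death"}
            elif iid in dropped_reasons:
                assert dropped_reasons[iid] in env_drop
        # kept records reproduce the oracle's per-mother outcome multiset
        expect = sorted(
            (m, y) for iid, (m, y) in want.items() if iid not in dropped_reasons
        )
        got = sorted(zip(table.df["female_id"], table.df["outcome"]))
        assert got == expect

    def test_infant_survival_example_cohort(self):
        """Six births: one censored, one maternal-death exclusion, one death
        at 69 weeks, three survivors -> 4 records with 3 successes."""
        start = pd.Timestamp("2000-01-01")
        data_end = pd.Timestamp("2004-01-01")
        females = pd.DataFrame(
            [{"female_id": f"F{k}", "mother_id": f"M{k}", "birth_date": start - pd.DateOffset(years=8),
              "death_date": pd.Timestamp("2000-06-01") if k == 1 else pd.NaT,
              "group_id": "g0"} for k in range(6)]
        )
        months = pd.period_range("2000-01", "2003-12", freq="M")
        states = pd.DataFrame(
            [{"female_id": f"F{k}", "month": m, "state": "postpartum-amenorrhea",
              "group_id": "g0"} for k in range(6) for m in months]
        )
        census = pd.DataFrame(
            [{"group_id": "g0", "month": m, "mean_size": 25.0} for m in months]
        )
        births = {
            0: ("2000-02-01", None),            # survivor
            1: ("2000-03-01", "2000-09-01"),    # mother died 2000-06 -> excluded
            2: ("2000-04-01", None),            # survivor
            3: ("2000-05-01", str((pd.Timestamp("2000-05-01") + pd.Timedelta(weeks=69)).date())),
            4: ("2003-10-01", None),            # not yet 70 weeks at data end
            5: ("2000-06-01", None),            # survivor
        }
        infants = pd.DataFrame(
            [{"infant_id": f"i{k}", "mother_id": f"F{k}",
              "birth_date": pd.Timestamp(b), "death_date": pd.Timestamp(d) if d else pd.NaT}
             for k, (b, d) in births.items()]
        )
        pregnancies = pd.DataFrame(
            columns=["female_id", "conception_date", "end_date", "live"]
        )
        ranks = RankSeries(pd.DataFrame(
            [{"female_id": f, "month": m, "rank": 0.5}
             for f in [f"F{k}" for k in range(6)] + [f"M{k}" for k in range(6)]
             for m in pd.period_range("1991-01", "2003-12", freq="M")]
        ))
        data = ReproData(females, states, pregnancies, infants, census)
        table, drops = build_infantsurvival_table(
            data, "rank", ranks=ranks, data_end=data_end
        )
        assert len(table) == 4
        assert int(table.df["outcome"].sum()) == 3
        assert set(drops["reason"]) == {"censored-infant", "maternal-death"}

    def test_infant_death_before_birth_is_integrity_error(self):
        data, rain, ranks, *_ = random_history(seed=2)
        data.infants.loc[len(data.infants)] = {
            "infant_id": "bad", "mother_id": "F00",
            "birth_date": pd.Timestamp("1992-01-01"),
            "death_date": pd.Timestamp("1991-01-01"),
        }
        with pytest.raises(DataIntegrityError):
            build_infantsurvival_table(data, "rank", ranks=ranks)


class TestRecordInvariants:
    @pytest.mark.parametrize("seed", [4, 17])
    @pytest.mark.parametrize("env", ["rank", "rain"])
    def test_delta_identities_and_ranges(self, seed, env):
        data, rain, ranks, *_ = random_history(seed=seed)
        table, _ = build_conception_table(data, env, rain=rain, ranks=ranks)
        df = table.df
        assert len(df) > 0
        # e0 + delta recovers e1 to one ulp; the magnitude identity is exact
        np.testing.assert_allclose(df["e0"] + df["delta"], df["e1"], rtol=1e-15, atol=0)
        np.testing.assert_array_equal(df["abs_delta"], df["delta"].abs())
        assert (df["outcome"].isin([0, 1])).all()
        assert (df["age"] > 0).all()
        if env == "rank":
            assert df["e0"].between(0, 1).all()
            assert df["e1"].between(0, 1).all()
            assert (df["abs_delta"] <= 1).all()
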
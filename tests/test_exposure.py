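"""Exceedance-day counting and person-days exposure aggregation."""

import numpy as np
import pandas as pd
import pytest

from hazardheat import exposure as expo


def make_wbgt_df(dates, values):
    return pd.DataFrame({"date": pd.DatetimeIndex(dates), "wbgt_max": values})


def make_facilities(rows):
    df = pd.DataFrame(
        rows,
        columns=["facility_id", "state", "facility_type", "population"],
    )
    df["name"] = df["facility_id"]
    df["lat"] = 0.0
    df["lon"] = 0.0
    df["population_year"] = 2018
    return df


def make_annual(unit_id, year_counts):
    return pd.DataFrame(
        {
            "unit_id": unit_id,
            "year": list(year_counts),
            "exceedance_days": list(year_counts.values()),
            "complete": True,
        }
    )


class TestCountExceedanceDays:
    def test_all_below_threshold(self, flat_year):
        df = make_wbgt_df(flat_year, np.full(len(flat_year), 27.9))
        count, complete = expo.count_exceedance_days(df, 2017)
        assert count == 0 and complete

    def test_all_above_threshold(self, flat_year):
        df = make_wbgt_df(flat_year, np.full(len(flat_year), 30.0))
        count, complete = expo.count_exceedance_days(df, 2017)
        assert count == 365 and complete

    @pytest.mark.parametrize("k", [0, 1, 75, 365])
    def test_planted_k_days_recovered(self, flat_year, k):
        vals = np.full(len(flat_year), 25.0)
        vals[:k] = 30.0
        df = make_wbgt_df(flat_year, vals)
        count, _ = expo.count_exceedance_days(df, 2017)
        assert count == k

    def test_exceeds_is_strict(self, flat_year):
        vals = np.full(len(flat_year), 28.0)  # exactly at the threshold
        df = make_wbgt_df(flat_year, vals)
        assert expo.count_exceedance_days(df, 2017)[0] == 0
        assert expo.count_exceedance_days(df, 2017, strict=False)[0] == 365

    def test_missing_day_flags_incomplete(self, flat_year):
        vals = np.full(len(flat_year), 30.0)
        vals[100] = np.nan
        df = make_wbgt_df(flat_year, vals)
        count, complete = expo.count_exceedance_days(df, 2017)
        assert count == 364 and not complete

    def test_leap_year_reaches_366(self):
        days = pd.date_range("2020-01-01", "2020-12-31", freq="D")
        df = make_wbgt_df(days, np.full(len(days), 30.0))
        count, complete = expo.count_exceedance_days(df, 2020)
        assert count == 366 and complete

    def test_absent_year_rejected(self, flat_year):
        df = make_wbgt_df(flat_year, np.full(len(flat_year), 30.0))
        with pytest.raises(ValueError, match="2019"):
            expo.count_exceedance_days(df, 2019)

    def test_threshold_monotonicity(self, flat_year, rng):
        vals = 20 + 12 * rng.random(len(flat_year))
        df = make_wbgt_df(flat_year, vals)
        counts = [expo.count_exceedance_days(df, 2017, threshold=t)[0]
                  for t in (26.0, 28.0, 30.0)]
        assert counts[0] >= counts[1] >= counts[2]


class TestMeanAnnualExceedance:
    def test_constant_counts(self):
        annual = make_annual("A", {y: 10 for y in range(2016, 2021)})
        assert expo.mean_annual_exceedance(annual, range(2016, 2021)) == 10

    def test_arithmetic_mean(self):
        annual = make_annual("A", dict(zip(range(2016, 2021), [0, 5, 10, 15, 20])))
        assert expo.mean_annual_exceedance(annual, range(2016, 2021)) == 10

    def test_random_counts_match_bruteforce(self, rng):
        counts = rng.integers(0, 200, size=5)
        annual = make_annual("A", dict(zip(range(2016, 2021), counts)))
        expected = sum(counts) / len(counts)
        assert expo.mean_annual_exceedance(
            annual, range(2016, 2021)
        ) == pytest.approx(expected)

    def test_missing_year_rejected(self):
        annual = make_annual("A", {2016: 1, 2017: 2})
        with pytest.raises(ValueError, match="missing"):
            expo.mean_annual_exceedance(annual, range(2016, 2021))

    def test_incomplete_year_rejected_by_default(self):
        annual = make_annual("A", {2016: 1, 2017: 2})
        annual.loc[1, "complete"] = False
        with pytest.raises(ValueError, match="incomplete"):
            expo.mean_annual_exceedance(annual, [2016, 2017])
        assert expo.mean_annual_exceedance(
            annual, [2016, 2017], require_complete=False
        ) == pytest.approx(1.5)


class TestPersonDays:
    def test_reference_product(self):
        # a 249-person facility averaging 126.2 hazardous days per year
        assert expo.person_days_exposure(249, 126.2) == pytest.approx(31423.8)

    def test_zero_days(self):
        assert expo.person_days_exposure(1, 0.0) == 0.0

    def test_population_must_be_positive(self):
        with pytest.raises(ValueError, match="population"):
            expo.person_days_exposure(0, 10.0)

    def test_linearity_in_population(self):
        assert expo.person_days_exposure(500, 12.5) == pytest.approx(
            2 * expo.person_days_exposure(250, 12.5)
        )


class TestAggregateExposure:
    window = range(2016, 2021)

    def _synthetic(self, rng, n=50):
        states = rng.choice(["AA", "AB", "AC"], size=n)
        types = rng.choice(list(expo.FACILITY_TYPES), size=n)
        pops = rng.integers(1, 2000, size=n)
        facs = make_facilities(
            [(f"F{i:03d}", states[i], types[i], pops[i]) for i in range(n)]
        )
        annual = pd.concat(
            [
                make_annual(
                    f"F{i:03d}",
                    dict(zip(self.window, rng.integers(0, 150, size=5))),
                )
                for i in range(n)
            ],
            ignore_index=True,
        )
        return facs, annual

    def test_single_facility_single_group(self):
        facs = make_facilities([("F0", "AA", "state_prison", 100)])
        annual = make_annual("F0", {y: 20 for y in self.window})
        table, excluded = expo.aggregate_exposure(facs, annual, self.window)
        assert len(table) == 1 and excluded.empty
        assert table["person_days"].iloc[0] == pytest.approx(100 * 20)
        assert table["share"].iloc[0] == pytest.approx(1.0)

    def test_shares_sum_to_one(self, rng):
        facs, annual = self._synthetic(rng)
        table, _ = expo.aggregate_exposure(facs, annual, self.window)
        assert table["share"].sum() == pytest.approx(1.0)

    def test_grouped_equals_bruteforce_double_loop(self, rng):
        facs, annual = self._synthetic(rng)
        table, _ = expo.aggregate_exposure(
            facs, annual, self.window, group_by=["state", "facility_type"]
        )
        for row in table.itertuples():
            total = 0.0
            for fac in facs.itertuples():
                if fac.state == row.state and fac.facility_type == row.facility_type:
                    sub = annual[annual["unit_id"] == fac.facility_id]
                    mean_days = sub[sub["year"].isin(self.window)][
                        "exceedance_days"
                    ].mean()
                    total += fac.population * mean_days
            assert row.person_days == pytest.approx(total)

    def test_conservation_across_groupings(self, rng):
        facs, annual = self._synthetic(rng)
        by_state, _ = expo.aggregate_exposure(
            facs, annual, self.window, group_by=["state"]
        )
        by_both, _ = expo.aggregate_exposure(
            facs, annual, self.window, group_by=["state", "facility_type"]
        )
        assert by_state["person_days"].sum() == pytest.approx(
            by_both["person_days"].sum()
        )

    def test_share_invariant_to_population_scaling(self, rng):
        facs, annual = self._synthetic(rng)
        table1, _ = expo.aggregate_exposure(facs, annual, self.window)
        facs2 = facs.copy()
        facs2["population"] = facs2["population"] * 7
        table2, _ = expo.aggregate_exposure(facs2, annual, self.window)
        assert np.allclose(table1["share"], table2["share"])

    def test_missing_series_names_facility(self):
        facs = make_facilities([("F0", "AA", "other", 10)])
        annual = make_annual("NOT_F0", {y: 1 for y in self.window})
        with pytest.raises(ValueError, match="F0"):
            expo.aggregate_exposure(facs, annual, self.window)

    def test_incomplete_facility_excluded_with_reason(self):
        facs = make_facilities(
            [("F0", "AA", "other", 10), ("F1", "AA", "other", 20)]
        )
        a0 = make_annual("F0", {y: 5 for y in self.window})
        a1 = make_annual("F1", {y: 5 for y in self.window})
        a1.loc[2, "complete"] = False
        table, excluded = expo.aggregate_exposure(
            facs, pd.concat([a0, a1]), self.window
        )
        assert excluded["facility_id"].tolist() == ["F1"]
        assert table["population"].sum() == 10


class TestTopExposed:
    window = range(2016, 2021)

    def test_planted_extreme_ranks_first(self, rng):
        facs = make_facilities(
            [(f"F{i}", "AA", "other", 10) for i in range(5)]
        )
        annual = pd.concat(
            [make_annual(f"F{i}", {y: int(rng.integers(0, 50)) for y in self.window})
             for i in range(4)]
            + [make_annual("F4", {y: 300 for y in self.window})],
            ignore_index=True,
        )
        ranked, n = expo.top_exposed_facilities(facs, annual, self.window)
        assert ranked["facility_id"].iloc[0] == "F4"
        assert n == 1  # only the extreme one averages >= 75 days

    def test_identical_facilities_threshold_count_all_or_none(self):
        facs = make_facilities([(f"F{i}", "AA", "other", 5) for i in range(3)])
        annual = pd.concat(
            [make_annual(f"F{i}", {y: 80 for y in self.window}) for i in range(3)],
            ignore_index=True,
        )
        _, n_hi = expo.top_exposed_facilities(
            facs, annual, self.window, min_days=75
        )
        _, n_lo = expo.top_exposed_facilities(
            facs, annual, self.window, min_days=100
        )
        assert n_hi == 3 and n_lo == 0

    def test_ties_break_by_facility_id(self):
        facs = make_facilities(
            [("FB", "AA", "other", 5), ("FA", "AA", "other", 5)]
        )
        annual = pd.concat(
            [make_annual(u, {y: 50 for y in self.window}) for u in ("FB", "FA")],
            ignore_index=True,
        )
        ranked, _ = expo.top_exposed_facilities(facs, annual, self.window)
        assert ranked["facility_id"].tolist() == ["FA", "FB"]


def test_unknown_facility_type_maps_to_other(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        assert expo.normalize_facility_type("SECURE JUVENILE") == "other"
    assert "SECURE JUVENILE" in caplog.text
    assert expo.normalize_facility_type(
        "COUNTY", {"COUNTY": "county_jail"}
    ) == "county_jail"
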
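"""Cost allocation, inflation, imputation and monthly aggregation."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from costtraj import ledger as lg

COSTS = lg.UnitCostTable(
    prices={"A": 100.0, "B": 25.0},
    cpi={2015: 100.0, 2016: 101.0, 2017: 102.0},
)


def _patients(survivals, death=date(2017, 1, 1)):
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(len(survivals))],
        "diagnosis_date": [death - timedelta(days=int(s)) for s in survivals],
        "death_date": [death] * len(survivals),
    })


class TestAllocation:
    def test_uniform_split_over_three_days(self):
        e = lg.ResourceEvent("P0", "medication", date(2017, 1, 1),
                             date(2017, 1, 3), 3.0, "A", 2017)
        daily = lg.allocate_event_daily(e, COSTS)
        assert len(daily) == 3
        assert all(abs(v - 100.0) < 1e-9 for v in daily.values())

    def test_single_day_event_maps_to_that_date(self):
        e = lg.ResourceEvent("P0", "consultation", date(2017, 2, 5), None,
                             2.5, "A", 2017)
        daily = lg.allocate_event_daily(e, COSTS)
        assert daily == {date(2017, 2, 5): pytest.approx(250.0)}

    def test_interval_split_and_zero_total(self):
        daily = lg.allocate_interval_costs(600.0, date(2017, 1, 1), date(2017, 1, 30))
        assert len(daily) == 30
        assert all(abs(v - 20.0) < 1e-12 for v in daily.values())
        zero = lg.allocate_interval_costs(0.0, date(2017, 1, 1), date(2017, 1, 5))
        assert all(v == 0.0 for v in zero.values())

    def test_empty_interval_raises(self):
        with pytest.raises(ValueError, match="empty interval"):
            lg.allocate_interval_costs(10.0, date(2017, 1, 2), date(2017, 1, 1))

    def test_unknown_cost_code_named_in_error(self):
        e = lg.ResourceEvent("P0", "medication", date(2017, 1, 1), None,
                             1.0, "NOPE", 2017)
        with pytest.raises(lg.UnknownCostCodeError, match="NOPE"):
            lg.allocate_event_daily(e, COSTS)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(total=st.floats(0, 1e5), span=st.integers(1, 400))
    def test_conservation_by_direct_summation(self, total, span):
        daily = lg.allocate_interval_costs(total, date(2016, 1, 1),
                                           date(2016, 1, 1) + timedelta(days=span - 1))
        assert sum(daily.values()) == pytest.approx(total, abs=1e-9 + 1e-12 * total)


class TestInflation:
    def test_identity_at_reference_year(self):
        assert lg.inflate_to_2017(100.0, 2017, COSTS) == pytest.approx(100.0)

    def test_cpi_ratio(self):
        costs = lg.UnitCostTable(prices={}, cpi={2015: 100.0, 2017: 102.0})
        assert lg.inflate_to_2017(100.0, 2015, costs) == pytest.approx(102.0)

    def test_missing_year_raises(self):
        with pytest.raises(ValueError, match="2003"):
            lg.inflate_to_2017(10.0, 2003, COSTS)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(amount=st.floats(0.01, 1e6), year=st.sampled_from([2015, 2016, 2017]))
    def test_inflate_deflate_round_trip(self, amount, year):
        up = lg.inflate_to_2017(amount, year, COSTS)
        back = up * COSTS.cpi[year] / COSTS.cpi[lg.REFERENCE_YEAR]
        assert back == pytest.approx(amount, rel=1e-12)


class TestImputation:
    def test_median_quantity_rule_and_flag(self):
        events = [
            lg.ResourceEvent("P0", "medication", date(2017, 1, 1), None, 2.0, "A", 2017),
            lg.ResourceEvent("P0", "medication", date(2017, 1, 2), None, None, "A", 2017),
        ]
        out = lg.impute_missing(events, lg.ImputePolicy())
        assert out[1].quantity == 2.0 and out[1].quantity_imputed
        assert not out[0].quantity_imputed

    def test_complete_events_returned_unchanged(self):
        events = [lg.ResourceEvent("P0", "diagnostic", date(2017, 1, 1), None,
                                   1.0, "B", 2016)]
        assert lg.impute_missing(events, lg.ImputePolicy()) == events

    def test_category_without_observations_raises(self):
        events = [lg.ResourceEvent("P0", "transfusion", date(2017, 1, 1), None,
                                   None, "A", 2017)]
        with pytest.raises(ValueError, match="transfusion"):
            lg.impute_missing(events, lg.ImputePolicy())

    def test_date_midpoint_rule_and_mass_masking(self):
        rng = np.random.default_rng(0)
        events = [
            lg.ResourceEvent("P0", "medication", date(2017, 1, 1), None,
                             float(q), "A", 2017)
            for q in rng.integers(1, 5, size=100)
        ]
        masked = rng.choice(100, size=20, replace=False)
        for k in masked:
            events[k].quantity = None
        events[3].start_date = None
        policy = lg.ImputePolicy(sequences={"P0": (date(2016, 1, 1), date(2017, 1, 1))})
        out = lg.impute_missing(events, policy)
        assert sum(e.quantity_imputed for e in out) == 20
        assert all(e.quantity is not None for e in out)
        assert out[3].start_date == date(2016, 7, 2)  # midpoint of 366 days
        assert out[3].dates_imputed


class TestMonthlyAggregation:
    def test_constant_daily_rate_full_year(self):
        patients = _patients([400])
        death = date(2017, 1, 1)
        daily = {"P0": {death - timedelta(days=k): 10.0 for k in range(1, 361)}}
        m = lg.aggregate_monthly(daily, patients)
        assert (m.values == 300).all()
        assert m.observed.all()

    def test_partial_final_month_for_short_survivor(self):
        # 75 days of life: months 1-2 fully observed, month 3 partial
        patients = _patients([75])
        death = date(2017, 1, 1)
        daily = {"P0": {death - timedelta(days=k): 10.0 for k in range(1, 76)}}
        m = lg.aggregate_monthly(daily, patients)
        assert m.observed[0, :3].all() and not m.observed[0, 3:].any()
        assert m.values[0, 0] == 300
        assert m.values[0, 1] == 300
        assert m.values[0, 2] == 150  # unadjusted partial sum (15 days)
        assert (m.values[0, 3:] == 0).all()

    def test_cost_outside_lifetime_raises_with_patient_and_date(self):
        patients = _patients([100])
        bad_day = date(2017, 1, 1) - timedelta(days=150)
        with pytest.raises(ValueError, match="P0.*2016-08-04"):
            lg.aggregate_monthly({"P0": {bad_day: 5.0}}, patients)

    def test_mask_consistency_invariant(self):
        survivals = [1, 29, 30, 31, 75, 90, 91, 360, 361, 2000]
        mask = lg.observation_mask(np.array(survivals))
        expect = [min(12, int(np.ceil(s / 30))) for s in survivals]
        assert list(mask.sum(axis=1)) == expect

    def test_random_ledger_conservation(self):
        rng = np.random.default_rng(42)
        survivals = rng.integers(40, 900, size=15)
        patients = _patients(list(survivals))
        death = date(2017, 1, 1)
        daily = {}
        total = 0.0
        for i, s in enumerate(survivals):
            day_map = {}
            for _ in range(40):
                k = int(rng.integers(0, min(360, s)))
                amt = float(rng.uniform(0, 500))
                d = death - timedelta(days=k)
                day_map[d] = day_map.get(d, 0.0) + amt
                total += amt
            daily[f"P{i}"] = day_map
        m = lg.aggregate_monthly(daily, patients)
        assert abs(m.values.sum() - total) <= 0.5 * m.observed.sum()

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        death = date(2016, 6, 1)
        shift = timedelta(days=137)
        patients_a = _patients([200], death=death)
        patients_b = _patients([200], death=death + shift)
        days = rng.integers(0, 200, size=30)
        amts = rng.uniform(0, 300, size=30)
        daily_a = {"P0": {}}
        daily_b = {"P0": {}}
        for k, a in zip(days, amts):
            da = death - timedelta(days=int(k))
            daily_a["P0"][da] = daily_a["P0"].get(da, 0.0) + a
            daily_b["P0"][da + shift] = daily_b["P0"].get(da + shift, 0.0) + a
        ma = lg.aggregate_monthly(daily_a, patients_a)
        mb = lg.aggregate_monthly(daily_b, patients_b)
        assert (ma.values == mb.values).all()
        assert (ma.observed == mb.observed).all()


class TestTrend:
    def test_constant_cohort(self):
        values = np.full((5, 12), 100)
        m = lg.MonthlyCostMatrix(values, np.ones((5, 12), bool),
                                 np.array([f"P{i}" for i in range(5)]))
        tr = lg.summarize_trend(m)
        assert (tr["mean"] == 100).all()
        assert (tr["sd"] == 0).all()
        assert tr["grand_mean"].iloc[0] == 100

    def test_single_patient_means_equal_row(self):
        values = np.arange(12)[None, :] + 1
        m = lg.MonthlyCostMatrix(values, np.ones((1, 12), bool), np.array(["P0"]))
        tr = lg.summarize_trend(m)
        assert list(tr["mean"]) == list(values[0].astype(float))
        assert tr["sd"].isna().all()

    def test_unobserved_month_reported_missing(self):
        values = np.zeros((3, 12), dtype=int)
        observed = np.zeros((3, 12), dtype=bool)
        observed[:, :2] = True  # all patients survive < 90 days
        m = lg.MonthlyCostMatrix(values, observed,
                                 np.array([f"P{i}" for i in range(3)]))
        tr = lg.summarize_trend(m)
        assert tr["mean"].iloc[2:].isna().all()
        assert tr["n"].iloc[2:].eq(0).all()


class TestMatrixIO:
    def test_csv_round_trip(self, tmp_path, cohort3):
        _, matrix, _ = cohort3
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        back = lg.MonthlyCostMatrix.from_csv(path)
        assert (back.values == matrix.values).all()
        assert (back.observed == matrix.observed).all()

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            lg.MonthlyCostMatrix(-np.ones((1, 12), int), np.ones((1, 12), bool),
                                 np.array(["P0"]))
        values = np.ones((1, 12), int)
        observed = np.ones((1, 12), bool)
        observed[0, 5] = False
        with pytest.raises(ValueError, match="unobserved"):
            lg.MonthlyCostMatrix(values, observed, np.array(["P0"]))
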
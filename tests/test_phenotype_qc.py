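"""Feeding-event QC: rule boundaries, bookkeeping invariants, daily sums and
the adjusted-intake trajectory."""

import numpy as np
import pandas as pd
import pytest

from mwgwas import (
    PenDayConfig,
    QcThresholds,
    adjusted_test_intake,
    daily_intake,
    filter_events,
    pen_day_flags,
    simulate_feeding_events,
)


class TestFilterEvents:
    def test_toy_set_hand_enumeration(self, toy_events):
        retained, rejections = filter_events(toy_events)
        # hand enumeration: rows 2 (duration = 3600 exactly), 3 (0.9 s),
        # 5 (3.5 kg), 6 (rate 2.5) are removed; 6 events survive
        assert len(retained) == 6
        assert sorted(rejections.index) == [2, 3, 5, 6]
        reasons = rejections["reasons"]
        assert reasons[2] == "duration"  # strict upper bound
        assert reasons[3] == "duration"
        assert reasons[5] == "amount"
        assert reasons[6] == "rate"

    def test_boundary_values_removed_strictly(self):
        ev = pd.DataFrame(
            {
                "animal_id": ["a"] * 4,
                "pen_id": ["p"] * 4,
                "day": [1] * 4,
                "duration_s": [3600.0, 1.0, 120.0, 60.0],
                "amount_kg": [1.0, 0.021, 0.020, 2.0],
            }
        )
        # 3600 s exactly, 1 s exactly, 0.020 kg exactly, rate exactly 2.0
        retained, rejections = filter_events(ev)
        assert len(retained) == 0
        assert set(rejections["reasons"]) == {"duration", "amount", "rate"}

    def test_good_event_retained(self):
        ev = pd.DataFrame(
            [["a", "p", 1, 120.0, 0.5]],
            columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"],
        )
        retained, rejections = filter_events(ev)
        assert len(retained) == 1 and len(rejections) == 0

    def test_unparseable_rejected_not_raised(self):
        ev = pd.DataFrame(
            [["a", "p", 1, np.nan, 0.5], ["a", "p", 1, 120.0, "oops"]],
            columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"],
        )
        retained, rejections = filter_events(ev)
        assert len(retained) == 0
        assert all("unparseable" in r for r in rejections["reasons"])

    def test_partition_and_idempotence(self):
        events, _ = simulate_feeding_events(n_animals=10, n_days=5, aberrant_fraction=0.3, seed=3)
        retained, rejections = filter_events(events)
        assert len(retained) + len(rejections) == len(events)
        assert (rejections["reasons"].str.len() > 0).all()
        again, rejected_again = filter_events(retained)
        assert len(rejected_again) == 0
        pd.testing.assert_frame_equal(again, retained)


class TestPenDayFlags:
    def test_clean_cells_unflagged(self):
        events, _ = simulate_feeding_events(n_animals=10, n_days=3, aberrant_fraction=0.0, seed=1)
        flags = pen_day_flags(events)
        assert not flags["flagged"].any()

    def test_aberrant_fraction_bound(self):
        # one pen-day with 3 of 6 events aberrant (50%) against a 20% bound
        good = [("a", "p1", 1, 300.0, 0.5)] * 3
        bad = [("a", "p1", 1, 4000.0, 0.5)] * 3
        other = [("b", "p2", 1, 300.0, 0.5)] * 4
        events = pd.DataFrame(
            good + bad + other,
            columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"],
        )
        flags = pen_day_flags(events, config=PenDayConfig(max_aberrant_fraction=0.2))
        flagged = flags.set_index(["pen_id", "day"])["flagged"]
        assert flagged[("p1", 1)]
        assert not flagged[("p2", 1)]
        stats = flags.set_index(["pen_id", "day"]).loc[("p1", 1)]
        assert stats["n_events"] == 6 and stats["n_aberrant"] == 3

    def test_empty_expected_cell_flagged_no_data(self):
        events = pd.DataFrame(
            [["a", "p1", 1, 300.0, 0.5]],
            columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"],
        )
        flags = pen_day_flags(events, expected=[("p1", 1), ("p1", 2)])
        row = flags.set_index(["pen_id", "day"]).loc[("p1", 2)]
        assert row["flagged"] and row["reasons"] == "no data"


class TestDailyIntake:
    def test_sums_per_animal_day(self):
        ev = pd.DataFrame(
            [["a", "p", 3, 100.0, 0.4], ["a", "p", 3, 100.0, 0.6]],
            columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"],
        )
        out = daily_intake(ev)
        assert len(out) == 1
        assert out.iloc[0]["intake_kg"] == pytest.approx(1.0)

    def test_empty_input(self):
        out = daily_intake(pd.DataFrame(columns=["animal_id", "pen_id", "day", "duration_s", "amount_kg"]))
        assert len(out) == 0

    def test_matches_independent_aggregation_and_order_invariance(self, rng):
        events, _ = simulate_feeding_events(n_animals=3, n_days=5, aberrant_fraction=0.0, seed=9)
        out = daily_intake(events)
        # independent oracle: plain dict accumulation
        acc = {}
        for row in events.itertuples(index=False):
            acc[(row.animal_id, row.day)] = acc.get((row.animal_id, row.day), 0.0) + row.amount_kg
        assert len(out) == len(acc)
        for row in out.itertuples(index=False):
            assert row.intake_kg == pytest.approx(acc[(row.animal_id, row.day)], abs=1e-12)
        shuffled = events.sample(frac=1.0, random_state=0).reset_index(drop=True)
        out2 = daily_intake(shuffled)
        pd.testing.assert_frame_equal(out, out2)


class TestAdjustedTestIntake:
    @staticmethod
    def _meta(animals, gender="barrow", pen="p1"):
        return pd.DataFrame(
            {"animal_id": animals, "gender": gender, "group_pen": pen}
        )

    def test_complete_data_no_effects_equals_raw_sum(self):
        daily = pd.DataFrame(
            {"animal_id": ["a"] * 5, "day": range(1, 6), "intake_kg": [1.0, 1.2, 1.1, 1.3, 1.4]}
        )
        res = adjusted_test_intake(daily, self._meta(["a"]), n_days=5)
        assert res.totals.iloc[0]["adjusted_intake_kg"] == pytest.approx(6.0)

    def test_constant_trajectory_imputes_missing_day(self):
        days = [d for d in range(1, 45) if d != 20]
        daily = pd.DataFrame({"animal_id": ["a"] * len(days), "day": days, "intake_kg": 2.0})
        res = adjusted_test_intake(daily, self._meta(["a"]), n_days=44)
        assert res.totals.iloc[0]["adjusted_intake_kg"] == pytest.approx(88.0, abs=1e-6)

    def test_known_gender_effect_removed(self, rng):
        # 20 animals, constant 2 kg/day baseline, gilts eat +0.5 kg/day
        animals = [f"an{i}" for i in range(20)]
        gender = ["barrow" if i < 10 else "gilt" for i in range(20)]
        rows = []
        for a, g in zip(animals, gender):
            for d in range(1, 11):
                base = 2.0 + (0.5 if g == "gilt" else 0.0)
                rows.append((a, d, base + 0.01 * rng.standard_normal()))
        daily = pd.DataFrame(rows, columns=["animal_id", "day", "intake_kg"])
        meta = pd.DataFrame({"animal_id": animals, "gender": gender, "group_pen": "p1"})
        res = adjusted_test_intake(daily, meta, n_days=10)
        totals = res.totals.merge(meta, on="animal_id")
        means = totals.groupby("gender")["adjusted_intake_kg"].mean()
        assert abs(means["barrow"] - means["gilt"]) < 0.1  # raw gap would be 5 kg

    def test_animal_with_zero_days_excluded(self):
        daily = pd.DataFrame({"animal_id": ["a"], "day": [1], "intake_kg": [2.0]})
        meta = self._meta(["a", "ghost"])
        res = adjusted_test_intake(daily, meta, n_days=3)
        assert "ghost" in res.excluded
        assert list(res.totals["animal_id"]) == ["a"]
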
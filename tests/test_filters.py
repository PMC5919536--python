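"""Observation extraction against hand-enumerated toy schedules."""

import numpy as np
import pytest

from antird import (
    DonorRecord,
    extract_peak_changes,
    extract_post_booster,
    filter_unboostered,
)


def make_record(donor_id, days, titers, boosters):
    return DonorRecord(
        donor_id=donor_id,
        obs_days=np.array(days, float),
        measured_titers=np.array(titers, float),
        booster_days=np.array(boosters, float),
    )


def regular_record(donor_id="d1", until=800, step=28, boosters=()):
    days = list(range(0, until + 1, step))
    titers = [10.0 + (i % 3) for i in range(len(days))]  # arbitrary pattern
    return make_record(donor_id, days, titers, boosters)


class TestFilterUnboostered:
    def test_two_boosters_reorigin(self):
        # boosters at 0 and 400; donations every 28 days to 784.
        # segment 1: eligible days in [100, 400) -> 112..392, origin 112
        # segment 2: eligible days >= 500 -> 504..784, origin 504
        rec = regular_record(until=784, boosters=[0.0, 400.0])
        out = filter_unboostered([rec], 100.0)
        seg1 = out[out.segment == 1]
        seg2 = out[out.segment == 2]
        assert seg1.origin_day.unique().tolist() == [112.0]
        expected1 = [d - 112 for d in range(140, 400, 28)]
        assert sorted(seg1.t.tolist()) == expected1
        assert seg2.origin_day.unique().tolist() == [504.0]
        expected2 = [d - 504 for d in range(532, 785, 28)]
        assert sorted(seg2.t.tolist()) == expected2
        # differences match the titer pattern exactly
        for _, row in out.iterrows():
            day = row.origin_day + row.t
            assert row.dc == rec.measured_titers[list(rec.obs_days).index(day)] - row.origin_titer

    def test_never_boostered_donor_fully_usable(self):
        rec = regular_record(until=280, boosters=[])
        out = filter_unboostered([rec], 100.0)
        assert out.origin_day.unique().tolist() == [0.0]
        assert len(out) == rec.n_obs - 1  # every later donation pairs with the origin

    def test_recent_booster_excludes_final_donation(self):
        # booster 50 days before the final donation: that donation is excluded
        rec = make_record("d1", [0, 100, 200, 250], [10, 9, 9, 8], boosters=[200.0])
        out = filter_unboostered([rec], 100.0)
        assert set(out.origin_day + out.t) == {100.0, 200.0}
        assert 250.0 not in set(out.origin_day + out.t)

    def test_booster_day_measurement_closes_its_segment(self):
        # the measurement at a booster day precedes the booster: it stays
        rec = make_record("d1", [0, 150, 300], [10, 9, 8], boosters=[300.0])
        out = filter_unboostered([rec], 100.0)
        assert 300.0 in set(out.origin_day + out.t)

    def test_requires_day_information(self):
        from antird import S1Record

        s1 = S1Record("x", np.array([10.0]), np.array([0]))
        with pytest.raises(ValueError, match="day"):
            filter_unboostered([s1])


class TestExtractPostBooster:
    def test_window_truncated_by_next_booster(self):
        rec = regular_record(until=400, boosters=[0.0, 150.0])
        out = extract_post_booster([rec])
        first = out[out.booster_day == 0.0]
        # open interval (0, 150): donations 28..140
        assert sorted(first.t.tolist()) == [28, 56, 84, 112, 140]

    def test_close_booster_window_dropped_entirely(self):
        rec = regular_record(until=400, boosters=[0.0, 56.0])
        out = extract_post_booster([rec])
        assert set(out.booster_day) == {0.0, 56.0} - {56.0} | {0.0}
        assert sorted(out[out.booster_day == 0.0].t.tolist()) == [28]
        assert 56.0 not in set(out.booster_day)  # < 100 days after previous

    def test_three_booster_enumeration(self):
        # donations every 28 days to 784; boosters at 0, 250, 600 (the last
        # two between donations); horizon 200; prior exclusion 100.
        # b1: donations in (0, 200] -> lags 28..196
        # b2: donations in (250, 450] -> 252..448, lags 2..198
        # b3: donations in (600, 784] -> 616..784, lags 16..184
        rec = regular_record(until=784, boosters=[0.0, 250.0, 600.0])
        out = extract_post_booster([rec])
        got = {b: sorted(g.t.tolist()) for b, g in out.groupby("booster_day")}
        assert got[0.0] == [d for d in range(28, 197, 28)]
        assert got[250.0] == [d for d in range(2, 199, 28)]
        assert got[600.0] == [d for d in range(16, 185, 28)]

    def test_origin_is_titer_at_boostering(self):
        rec = make_record("d1", [0, 28, 56], [5, 7, 9], boosters=[0.0])
        out = extract_post_booster([rec])
        assert set(out.origin_titer) == {5.0}
        assert sorted(out.dc.tolist()) == [2.0, 4.0]


class TestExtractPeakChanges:
    def test_first_measurement_in_window(self):
        rec = make_record("d1", [0, 28, 42, 70], [5, 8, 9, 9], boosters=[0.0])
        out = extract_peak_changes([rec])
        assert len(out) == 1
        assert out.iloc[0].t == 28 and out.iloc[0].dc == 3.0 and out.iloc[0].start == 5.0

    def test_pre_exclusion_50_days(self):
        # second booster 40 days after the first is excluded; third (120 days
        # later) qualifies
        rec = make_record(
            "d1", [0, 40, 160, 190, 220], [5, 7, 8, 9, 9], boosters=[0.0, 40.0, 160.0]
        )
        out = extract_peak_changes([rec])
        assert set(out.booster_day) == {0.0, 160.0}
        got = out.set_index("booster_day")
        assert got.loc[0.0].t == 40 and got.loc[0.0].dc == 2.0
        assert got.loc[160.0].t == 30 and got.loc[160.0].dc == 1.0

    def test_subsequent_boosters_not_excluded(self):
        # a later booster inside the window does not disqualify the pair
        rec = make_record("d1", [0, 28, 42], [5, 8, 10], boosters=[0.0, 28.0])
        out = extract_peak_changes([rec])
        row = out[out.booster_day == 0.0].iloc[0]
        assert row.t == 28 and row.dc == 3.0

    def test_no_measurement_in_window_skips_booster(self):
        rec = make_record("d1", [0, 14, 70], [5, 7, 9], boosters=[0.0])
        out = extract_peak_changes([rec])
        assert len(out) == 0
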
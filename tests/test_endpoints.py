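import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from huttrial import published
from huttrial.endpoints import (
    EmptyDataError,
    death_count,
    killing_effect_control_adjusted,
    killing_effect_methods,
    killing_effect_table,
    summarize_arm,
)
from huttrial.records import FateCounts, HutNightRecord


@pytest.mark.parametrize(
    "counts, expected",
    [
        (FateCounts(4, 3, 1, 2), 8),
        (FateCounts(0, 0, 0, 0), 0),
        # trapped mosquitoes count as killed even when collected alive
        (FateCounts(5, 0, 0, 0), 5),
        (FateCounts(0, 0, 3, 7), 3),
    ],
)
def test_death_count(counts, expected):
    assert death_count(counts) == expected


class TestSummarizeArm:
    def test_hand_fixture_totals_and_moments(self, hand_records):
        s = summarize_arm(hand_records, "T-LLIN", "an_gambiae")
        assert (s.n_hut_nights, s.total_entry, s.total_death) == (2, 11, 9)
        assert s.trapped_total == 5
        assert s.mean_daily_entry == pytest.approx(5.5)
        assert s.mean_daily_entry * s.n_hut_nights == s.total_entry
        assert s.sd_daily_entry == pytest.approx(np.std([7, 4], ddof=1))
        assert s.sd_daily_death == pytest.approx(np.std([6, 3], ddof=1))
        assert s.mortality_pct == pytest.approx(100 * 9 / 11)
        assert s.trap_attributable_pct == pytest.approx(100 * 5 / 9)

    def test_two_equal_nights_give_zero_sd(self):
        recs = [
            HutNightRecord(n, 1, 1, "A", "an_gambiae", FateCounts(0, 7, 0, 0))
            for n in (1, 2)
        ]
        s = summarize_arm(recs, "A")
        assert s.mortality_pct == 100.0
        assert s.sd_daily_entry == 0.0 and s.sd_daily_death == 0.0

    def test_no_hut_nights_is_an_error(self, hand_records):
        with pytest.raises(EmptyDataError):
            summarize_arm(hand_records, "IG2")

    def test_zero_death_arm_has_zero_trap_share(self):
        recs = [
            HutNightRecord(1, 1, 1, "A", "an_gambiae", FateCounts(0, 0, 0, 5)),
            HutNightRecord(2, 1, 1, "A", "an_gambiae", FateCounts(0, 0, 0, 3)),
        ]
        s = summarize_arm(recs, "A")
        assert s.total_death == 0 and s.trap_attributable_pct == 0.0

    def test_totals_invariant_under_record_order(self, hand_records):
        shuffled = hand_records[:]
        random.Random(5).shuffle(shuffled)
        assert summarize_arm(shuffled, "PN2.0") == summarize_arm(
            hand_records, "PN2.0"
        )

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)),
            min_size=1,
            max_size=15,
        ).filter(lambda rows: any(e + d > 0 for d, e in rows))
    )
    def test_pooled_mortality_is_entry_weighted_mean(self, rows):
        # rows are (deaths, extra survivors) per hut-night
        recs = [
            HutNightRecord(
                i + 1, 1, 1, "A", "an_gambiae", FateCounts(0, d, 0, e)
            )
            for i, (d, e) in enumerate(rows)
        ]
        s = summarize_arm(recs, "A")
        entries = [d + e for d, e in rows]
        weighted = sum(
            (100 * d / (d + e)) * (d + e) for d, e in rows if d + e > 0
        ) / sum(entries)
        assert s.mortality_pct == pytest.approx(weighted)


class TestKillingEffect:
    def test_methods_variant_worked_values(self):
        assert killing_effect_methods(678, 413, 509).value_pct == pytest.approx(
            100 * 265 / 509
        )
        assert killing_effect_methods(678, 535, 611).value_pct == pytest.approx(
            100 * 143 / 611
        )
        assert killing_effect_methods(5, 5, 99).value_pct == 0.0

    def test_control_adjusted_worked_values(self):
        assert killing_effect_control_adjusted(
            678, 413, 118, 450
        ).value_pct == pytest.approx(100 * 265 / 450)
        assert killing_effect_control_adjusted(
            678, 505, 118, 450
        ).value_pct == pytest.approx(100 * 173 / 450)

    def test_zero_denominators_rejected(self):
        with pytest.raises(ZeroDivisionError):
            killing_effect_methods(1, 1, 0)
        with pytest.raises(ZeroDivisionError):
            killing_effect_control_adjusted(1, 1, 0, 0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(0, 2000),
        st.integers(0, 2000),
        st.integers(0, 2000),
        st.integers(0, 2000),
        st.integers(1, 2000),
    )
    def test_control_kill_count_cancels(self, kc, kr, ku1, ku2, tu):
        # the control-adjusted value does not depend on the control
        # kill count: the formula simplifies to 100*(k_cand - k_ref)/t_un
        a = killing_effect_control_adjusted(kc, kr, ku1, tu).value_pct
        b = killing_effect_control_adjusted(kc, kr, ku2, tu).value_pct
        assert a == pytest.approx(b)
        assert a == pytest.approx(100 * (kc - kr) / tu)

    def test_candidate_equals_reference_gives_zero(self):
        assert killing_effect_control_adjusted(42, 42, 7, 99).value_pct == 0.0


class TestKillingEffectTable:
    def test_published_totals_both_variants(self):
        sums = published.published_summaries()
        adj = killing_effect_table(
            sums, "T-LLIN", ["PN2.0", "Tsara boost", "IG2"],
            untreated_arm="untreated", variant="control_adjusted",
        )
        got = {e.reference_arm: e.value_pct for e in adj}
        assert got["PN2.0"] == pytest.approx(58.888, abs=1e-3)
        assert got["Tsara boost"] == pytest.approx(38.444, abs=1e-3)
        assert got["IG2"] == pytest.approx(31.778, abs=1e-3)

        met = killing_effect_table(
            sums, "T-LLIN", ["PN2.0", "Tsara boost", "IG2"],
            variant="methods",
        )
        got = {e.reference_arm: e.value_pct for e in met}
        assert got["PN2.0"] == pytest.approx(52.063, abs=1e-3)
        assert got["Tsara boost"] == pytest.approx(24.785, abs=1e-3)
        assert got["IG2"] == pytest.approx(23.404, abs=1e-3)

    def test_candidate_as_its_own_reference_is_zero(self):
        sums = published.published_summaries()
        (e,) = killing_effect_table(
            sums, "T-LLIN", ["T-LLIN"], untreated_arm="untreated"
        )
        assert e.value_pct == 0.0

    def test_missing_arm_is_a_lookup_error(self):
        sums = published.published_summaries()
        with pytest.raises(KeyError):
            killing_effect_table(sums, "T-LLIN", ["nope"],
                                 untreated_arm="untreated")


def test_death_never_exceeds_entry(hand_records):
    for r in hand_records:
        assert death_count(r.counts) <= r.counts.total_entry
        assert math.isfinite(r.counts.total_entry)
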
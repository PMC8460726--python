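"""Outcome classification and the screen's frequency statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pescreen.quantify import (Outcome, OutcomeCounts, SubstitutionWindow,
                               adjusted_fold_change, classify_read,
                               coverage_filter, endogenous_frequencies,
                               fold_change_table, library_efficiency,
                               stratify_by_pe2, substitution_window_counts,
                               tally_pair, unintended_substitution_rate)
from pescreen.synthetic import ScreenTruth, simulate_reads

import pandas as pd

from conftest import make_read, make_toy_pair


class TestClassifyRead:
    def test_exact_edited_region_is_intended(self, toy_pair):
        assert classify_read(make_read(toy_pair), toy_pair) is Outcome.INTENDED

    def test_exact_wildtype_region(self, toy_pair):
        read = make_read(toy_pair, region=toy_pair.wide_target)
        assert classify_read(read, toy_pair) is Outcome.WILDTYPE

    def test_intended_plus_extra_substitution_is_unintended(self, toy_pair):
        region = toy_pair.edited_wide_target
        region = region[:2] + ("A" if region[2] != "A" else "C") + region[3:]
        assert classify_read(make_read(toy_pair, region), toy_pair) is Outcome.UNINTENDED_EDIT

    def test_two_nt_deletion_is_indel(self, toy_pair):
        region = toy_pair.wide_target[:30] + toy_pair.wide_target[32:]
        assert classify_read(make_read(toy_pair, region), toy_pair) is Outcome.INDEL

    def test_intended_insertion_alone_is_intended(self):
        pair = make_toy_pair("insertion")
        assert classify_read(make_read(pair), pair) is Outcome.INTENDED

    def test_intended_edit_plus_extra_indel_is_indel(self, toy_pair):
        region = toy_pair.edited_wide_target
        region = region[:5] + region[6:]  # extra 1-nt deletion
        assert classify_read(make_read(toy_pair, region), toy_pair) is Outcome.INDEL

    def test_unlocatable_region_is_discarded(self, toy_pair):
        read = toy_pair.wide_target + toy_pair.upstream4 + toy_pair.barcode
        assert classify_read(read, toy_pair) is Outcome.DISCARD


class TestTally:
    def test_counts_partition_and_sum(self, toy_pair):
        reads = [make_read(toy_pair)] * 30 + \
                [make_read(toy_pair, toy_pair.wide_target)] * 70
        counts = tally_pair(reads, toy_pair)
        assert (counts.n_total, counts.n_intended, counts.n_unintended_edit,
                counts.n_indel, counts.n_wildtype) == (100, 30, 0, 0, 70)

    def test_no_reads_gives_all_zero(self, toy_pair):
        counts = tally_pair([], toy_pair)
        assert counts.n_total == 0 and counts.n_discarded == 0

    def test_planted_rates_recovered_within_3_binomial_sd(self, small_library):
        """depth 5,000 at planted intended 12% / indel 3%."""
        pairs = small_library.pairs[:4]
        truth = ScreenTruth.uniform([p.pair_id for p in pairs],
                                    intended=0.12, indel=0.03, depth=5000)
        by_id = {p.pair_id: p for p in pairs}
        grouped = {p.pair_id: [] for p in pairs}
        for read, pid, _ in simulate_reads(pairs, truth, seed=13):
            grouped[pid].append(read.sequence)
        for pid, seqs in grouped.items():
            counts = tally_pair(seqs, by_id[pid])
            for rate, n in ((0.12, counts.n_intended), (0.03, counts.n_indel)):
                sd = np.sqrt(rate * (1 - rate) * 5000)
                assert abs(n - rate * 5000) < 3 * sd


class TestFrequencies:
    @pytest.mark.parametrize("intended,total,expected", [
        (30, 100, 30.0), (0, 250, 0.0), (1, 3, 100.0 / 3.0)])
    def test_library_efficiency(self, intended, total, expected):
        counts = OutcomeCounts("p", n_intended=intended,
                               n_wildtype=total - intended)
        assert library_efficiency(counts) == pytest.approx(expected)

    def test_zero_total_marks_pair_undefined(self):
        assert library_efficiency(OutcomeCounts("p")) is None

    def test_endogenous_frequencies_formulae(self):
        counts = OutcomeCounts("p", n_intended=5, n_unintended_edit=2,
                               n_indel=1, n_wildtype=92)
        assert endogenous_frequencies(counts) == (5.0, 2.0, 1.0)

    def test_endogenous_matches_brute_force_recount(self, small_library):
        """Frequencies equal an independent per-read recount."""
        pairs = small_library.pairs[:3]
        # no sequencing error: every planted read survives to the tally
        truth = ScreenTruth.uniform([p.pair_id for p in pairs], depth=400,
                                    seq_error_rate=0.0)
        by_id = {p.pair_id: p for p in pairs}
        grouped = {p.pair_id: [] for p in pairs}
        for read, pid, label in simulate_reads(pairs, truth, seed=17):
            grouped[pid].append((read.sequence, label))
        for pid, rows in grouped.items():
            counts = tally_pair([s for s, _ in rows], by_id[pid])
            # oracle: recount the planted labels directly
            n = len(rows)
            expect = tuple(100.0 * sum(1 for _, l in rows if l == want) / n
                           for want in ("intended", "unintended", "indel"))
            assert endogenous_frequencies(counts) == pytest.approx(expect)

    def test_library_and_endogenous_intended_agree(self):
        counts = OutcomeCounts("p", n_intended=17, n_unintended_edit=3,
                               n_indel=5, n_wildtype=75)
        assert library_efficiency(counts) == pytest.approx(
            endogenous_frequencies(counts)[0])


class TestSubstitutionWindow:
    def test_all_zero_counts_give_zero_rate(self):
        win = SubstitutionWindow()
        assert unintended_substitution_rate(win, 100) == 0.0

    def test_constant_counts(self):
        win = SubstitutionWindow()
        for o in win.counts:
            win.counts[o] = 7
        assert unintended_substitution_rate(win, 200) == pytest.approx(100 * 7 / 200)

    def test_window_has_36_positions(self):
        assert len(SubstitutionWindow().counts) == 36

    def test_random_counts_equal_direct_mean(self):
        rng = np.random.default_rng(3)
        win = SubstitutionWindow()
        vals = rng.integers(0, 50, size=len(win.counts))
        for o, v in zip(sorted(win.counts), vals):
            win.counts[o] = int(v)
        expected = 100.0 * float(np.mean(vals)) / 1000
        assert unintended_substitution_rate(win, 1000) == pytest.approx(expected)

    def test_empty_window_is_error(self):
        win = SubstitutionWindow(counts={})
        with pytest.raises(ValueError):
            unintended_substitution_rate(win, 10)

    def test_counts_skip_intended_edit_and_indel_reads(self, toy_pair):
        nick = toy_pair.nick_index
        wide = toy_pair.wide_target
        pos = nick + 5
        sub = wide[:pos] + ("A" if wide[pos] != "A" else "C") + wide[pos + 1:]
        reads = [make_read(toy_pair, sub),
                 make_read(toy_pair),  # intended: its edit is not a count
                 make_read(toy_pair, wide[:30] + wide[32:])]  # indel skipped
        win = substitution_window_counts(reads, toy_pair)
        assert win.counts[5] == 1
        assert sum(win.counts.values()) == 1


class TestCoverageFilter:
    def test_99_reads_excluded_100_retained(self):
        low = OutcomeCounts("low", n_wildtype=99)
        high = OutcomeCounts("high", n_wildtype=100)
        assert coverage_filter([low, high]) == [high]

    def test_discarded_reads_do_not_rescue_coverage(self):
        c = OutcomeCounts("p", n_wildtype=99, n_discarded=50)
        assert coverage_filter([c]) == []

    def test_mixed_table_matches_independent_filter(self, small_library):
        rng = np.random.default_rng(5)
        counts = [OutcomeCounts(p.pair_id, n_wildtype=int(rng.integers(0, 300)))
                  for p in small_library.pairs]
        kept = coverage_filter(counts, min_reads=120)
        assert kept == [c for c in counts if c.n_total >= 120]


class TestAdjustedFoldChange:
    def test_low_efficiency_example_damped_to_2p2(self):
        assert float(f"{adjusted_fold_change(0.015, 0.15):.2g}") == 2.2

    def test_high_efficiency_example_9p4(self):
        assert float(f"{adjusted_fold_change(1.5, 15.0):.2g}") == 9.4

    @given(x=st.floats(min_value=0, max_value=100))
    def test_equal_efficiencies_give_unity(self, x):
        assert adjusted_fold_change(x, x) == pytest.approx(1.0)

    def test_zero_zero_rescued_by_pseudocount(self):
        assert adjusted_fold_change(0.0, 0.0) == pytest.approx(1.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            adjusted_fold_change(-0.1, 5.0)

    @given(pe2=st.floats(min_value=0, max_value=50),
           hy=st.floats(min_value=0, max_value=50),
           delta=st.floats(min_value=0.01, max_value=10))
    def test_monotone_in_both_arguments(self, pe2, hy, delta):
        base = adjusted_fold_change(pe2, hy)
        assert adjusted_fold_change(pe2, hy + delta) > base
        assert adjusted_fold_change(pe2 + delta, hy) < base

    def test_approaches_raw_fold_far_from_pseudocount(self):
        raw = 30.0 / 10.0
        assert adjusted_fold_change(10.0, 30.0) == pytest.approx(raw, rel=0.01)


class TestStratifyByPE2:
    def make_records(self, pe2_values, hype2=5.0):
        df = pd.DataFrame({"pair_id": [f"p{i}" for i in range(len(pe2_values))],
                           "pe2_pct": pe2_values, "hype2_pct": hype2})
        return fold_change_table(df)

    def test_boundary_1pct_is_high(self):
        strata = stratify_by_pe2(self.make_records([1.0]))
        assert len(strata["high"]) == 1 and not strata["low"]

    def test_0p99_is_low(self):
        strata = stratify_by_pe2(self.make_records([0.99]))
        assert len(strata["low"]) == 1 and not strata["high"]

    def test_rescued_subset_counts_hype2_over_1pct(self):
        df = pd.DataFrame({"pair_id": ["a", "b"], "pe2_pct": [0.5, 0.5],
                           "hype2_pct": [2.0, 0.2]})
        strata = stratify_by_pe2(fold_change_table(df))
        assert [r.pair_id for r in strata["rescued"]] == ["a"]

    def test_partition_sizes_match_independent_count(self):
        rng = np.random.default_rng(11)
        pe2 = rng.uniform(0, 5, size=200)
        strata = stratify_by_pe2(self.make_records(list(pe2)))
        assert len(strata["high"]) == int((pe2 >= 1.0).sum())
        assert len(strata["low"]) == int((pe2 < 1.0).sum())
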
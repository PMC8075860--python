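import math
import random

import pytest
from hypothesis import given, strategies as st

from itdcall.clones import (
    apply_filters,
    ar_to_vaf,
    compute_coverage,
    compute_vaf,
    merge_calls,
    track_clones,
    vaf_to_ar,
)
from itdcall.clones import CloneRecord
from itdcall.detect import InsertCandidate, ITDCall
from itdcall.reference import RunConfig


def _call(seq, ref_pos, trailing=False, side="", estimate=None, read_offset=100):
    cand = InsertCandidate(seq, ref_pos=ref_pos, read_offset=read_offset,
                           trailing=trailing, side=side)
    est = estimate if estimate is not None else len(seq)
    return ITDCall(cand, ref_pos - len(seq), ref_pos, est, not trailing, 0)


class TestMergeCalls:
    def test_identical_inserts_merge(self, cfg):
        calls = [(_call("ACGTACGTACGTACGTACGTA", 150), 10),
                 (_call("ACGTACGTACGTACGTACGTA", 150), 5)]
        (clone,) = merge_calls(calls, cfg)
        assert clone.supporting_reads == 15
        assert clone.supporting_unique == 2

    def test_different_lengths_stay_separate(self, cfg):
        calls = [(_call("A" * 21, 30), 3), (_call("A" * 24, 30), 3)]
        assert len(merge_calls(calls, cfg)) == 2

    def test_different_sequences_stay_separate(self, cfg):
        calls = [(_call("ACGTAC", 150), 3), (_call("ACGTAT", 150), 3)]
        assert len(merge_calls(calls, cfg)) == 2

    def test_trailing_estimates_within_tolerance_merge(self, cfg):
        a = _call("ACGTACGTACGTACGTACGT", 150, trailing=True, side="right",
                  estimate=125)
        b = _call("ACGTACGTACGTACGT", 150, trailing=True, side="right",
                  estimate=126)
        (clone,) = merge_calls([(a, 4), (b, 2)], cfg)
        assert clone.trailing and clone.supporting_reads == 6
        # consensus is the most supported (here also longer) insert
        assert clone.consensus_insert == a.insert.sequence

    def test_trailing_never_merges_with_exact_by_default(self, cfg):
        a = _call("ACGTACGTACGTACGTACGTA", 150)
        b = _call("ACGTACGTACGTACGTACGTA", 150, trailing=True, side="right",
                  estimate=21)
        assert len(merge_calls([(a, 4), (b, 2)], cfg)) == 2

    def test_clone_count_never_exceeds_call_count(self, cfg):
        rng = random.Random(41)
        calls = [
            (_call("".join(rng.choice("ACGT") for _ in range(8)),
                   rng.randint(100, 110)), 1)
            for _ in range(50)
        ]
        assert len(merge_calls(calls, cfg)) <= 50

    def test_empty(self, cfg):
        assert merge_calls([], cfg) == []


class TestCoverage:
    def test_full_length_reads_cover_interior(self):
        assert compute_coverage([(0, 250, 100)], 150, 600) == 100

    def test_read_ending_at_flank_not_counted(self):
        # spans require both ref[p-1] and ref[p]
        assert compute_coverage([(0, 150, 10)], 150, 600) == 0
        assert compute_coverage([(0, 151, 10)], 150, 600) == 10

    def test_boundary_positions_use_single_flank(self):
        assert compute_coverage([(0, 10, 7)], 0, 600) == 7
        assert compute_coverage([(590, 600, 7)], 600, 600) == 7

    def test_matches_per_read_oracle(self):
        rng = random.Random(42)
        spans = [
            (s := rng.randint(0, 300), s + rng.randint(1, 300), rng.randint(1, 9))
            for _ in range(200)
        ]
        for p in (0, 1, 137, 300, 600):
            lo, hi = max(p - 1, 0), min(p + 1, 600)
            want = sum(c for s, e, c in spans if s <= lo and e >= hi)
            assert compute_coverage(spans, p, 600) == want


class TestVafAr:
    @pytest.mark.parametrize(
        "support,coverage,expected",
        [(67_000, 100_000, 0.67), (0, 1000, 0.0), (67, 1_000_000, 6.7e-5)],
    )
    def test_vaf(self, support, coverage, expected):
        assert compute_vaf(support, coverage) == pytest.approx(expected)

    def test_vaf_rejects_bad_input(self):
        with pytest.raises(ValueError):
            compute_vaf(5, 0)
        with pytest.raises(ValueError):
            compute_vaf(11, 10)

    @pytest.mark.parametrize("vaf,ar", [(0.5, 1.0), (0.0, 0.0), (1 / 3, 0.5)])
    def test_conversion_examples(self, vaf, ar):
        assert vaf_to_ar(vaf) == pytest.approx(ar)
        assert ar_to_vaf(ar) == pytest.approx(vaf)

    def test_vaf_one_gives_infinite_ar(self):
        assert math.isinf(vaf_to_ar(1.0))
        assert ar_to_vaf(math.inf) == 1.0

    @given(st.floats(0.0, 0.99))
    def test_round_trip(self, vaf):
        assert ar_to_vaf(vaf_to_ar(vaf)) == pytest.approx(vaf, abs=1e-12)


def _clone(seq="ACGTACGTACGTACGTACGTA", pos=150, support=10, vaf=0.1,
           trailing=False, length=None):
    return CloneRecord(
        consensus_insert=seq,
        length_estimate=length or len(seq),
        ref_pos=pos,
        trailing=trailing,
        supporting_reads=support,
        supporting_unique=1,
        coverage=max(support, 1),
        vaf=vaf,
    )


class TestApplyFilters:
    def test_support_filter(self, cfg):
        kept, audit = apply_filters([_clone(support=1), _clone(support=20)], cfg)
        assert len(kept) == 1 and kept[0].supporting_reads == 20
        assert audit[0][1] == "support"

    def test_no_vaf_floor_by_default(self, cfg):
        # 20 reads out of 300,000 pass: detection limit comes from support
        clone = _clone(support=20, vaf=20 / 300_000)
        kept, audit = apply_filters([clone], cfg)
        assert kept == [clone] and audit == []

    def test_empty(self, cfg):
        assert apply_filters([], cfg) == ([], [])

    def test_single_mate_support_at_dual_site_filtered(self, cfg):
        clone = _clone(support=10)
        clone.mate_support.update({1: 10})
        kept, audit = apply_filters([clone], cfg, {150: {1, 2}})
        assert kept == [] and audit[0][1] == "single_mate"
        cfg.require_both_mates = False
        kept, _ = apply_filters([clone], cfg, {150: {1, 2}})
        assert kept == [clone]


class TestTrackClones:
    def test_categories(self, cfg):
        persisting = _clone(seq="A" * 21, pos=100)
        lost = _clone(seq="C" * 24, pos=200)
        gained = _clone(seq="G" * 27, pos=300)
        dx = [persisting, lost]
        mid = []
        rl = [_clone(seq="A" * 21, pos=100, vaf=0.02), gained]
        trajectories = track_clones([dx, mid, rl], ["dx", "cy2", "rl"], cfg)
        by_cat = {t.category: t for t in trajectories}
        assert set(by_cat) == {"persisting", "lost", "gained"}
        assert by_cat["persisting"].vafs == [0.1, None, 0.02]
        assert by_cat["lost"].vafs == [0.1, None, None]
        assert by_cat["gained"].vafs == [None, None, 0.1]

    def test_categories_partition(self, cfg):
        rng = random.Random(43)
        samples = [
            [_clone(seq="ACGTACGTAC" * 2, pos=rng.choice([100, 200, 300]))
             for _ in range(rng.randint(0, 3))]
            for _ in range(4)
        ]
        trajectories = track_clones(samples, cfg=cfg)
        for t in trajectories:
            assert t.category in {"persisting", "lost", "gained", "transient"}
            assert any(v is not None for v in t.vafs)

    def test_requires_two_samples(self, cfg):
        with pytest.raises(ValueError):
            track_clones([[_clone()]], cfg=cfg)
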
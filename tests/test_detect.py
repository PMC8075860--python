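import random

import pytest

from helpers import mutate, random_dna
from itdcall.align import align_semi_global
from itdcall.detect import (
    InsertCandidate,
    classify_trailing,
    estimate_trailing_length,
    extract_inserts,
    find_tandem,
)
from itdcall.simulate import ITDSpec, make_itd_allele


def _detect(read, ref, cfg):
    """align -> extract -> verify; returns the list of ITD calls."""
    aln = align_semi_global(read, ref, cfg)
    calls = []
    for cand in extract_inserts(aln, cfg.min_insert_length):
        call = find_tandem(cand, ref, cfg)
        if call is not None:
            calls.append(call)
    return calls


class TestExtractInserts:
    def test_identity_alignment_has_no_candidates(self, ref, cfg):
        aln = align_semi_global(ref.sequence[:250], ref, cfg)
        assert extract_inserts(aln, 6) == []

    def test_21bp_gap_run_becomes_candidate(self, ref, cfg):
        read = make_itd_allele(ref, ITDSpec(129, 21))[:250]
        aln = align_semi_global(read, ref, cfg)
        (cand,) = extract_inserts(aln, 6)
        assert cand.length == 21 and not cand.trailing

    def test_below_minimum_discarded(self, ref, cfg):
        read = make_itd_allele(ref, ITDSpec(145, 5))[:250]
        aln = align_semi_global(read, ref, cfg)
        assert extract_inserts(aln, 6) == []
        # the same 5 bp insert is reported when the minimum allows it
        assert len(extract_inserts(aln, 5)) == 1


class TestClassifyTrailing:
    def test_centered_insert_is_not_trailing(self):
        cand = InsertCandidate("A" * 21, ref_pos=150, read_offset=115, trailing=False)
        assert not classify_trailing(cand, 250)

    def test_insert_reaching_read_end_is_trailing(self):
        cand = InsertCandidate("A" * 126, ref_pos=150, read_offset=124, trailing=False)
        assert classify_trailing(cand, 250)

    def test_insert_at_read_start_is_trailing(self):
        cand = InsertCandidate("A" * 198, ref_pos=30, read_offset=0, trailing=False)
        assert classify_trailing(cand, 250)

    def test_duplications_longer_than_half_read_come_out_trailing(self, ref, cfg):
        """2L > read length leaves no anchored geometry: calls are trailing."""
        for L, offset in [(126, 0), (126, 88), (198, 0)]:
            spec = ITDSpec(24 if L == 126 else 22, L)
            allele = make_itd_allele(ref, spec)
            read = allele[offset : offset + 250]
            calls = _detect(read, ref, cfg)
            assert calls and all(c.insert.trailing for c in calls)
            assert all(not c.exact_length for c in calls)


class TestFindTandem:
    def test_adjacent_upstream_duplication(self, ref, cfg):
        p = 150
        insert = ref.sequence[p - 21 : p]
        cand = InsertCandidate(insert, ref_pos=p, read_offset=100, trailing=False)
        call = find_tandem(cand, ref, cfg)
        assert (call.tandem_start, call.tandem_end) == (p - 21, p)
        assert call.mismatches_in_tandem == 0
        assert call.exact_length and call.length_estimate == 21

    def test_random_insert_is_not_an_itd(self, ref, cfg):
        rng = random.Random(31)
        for _ in range(20):
            cand = InsertCandidate(
                random_dna(rng, 10), ref_pos=150, read_offset=100, trailing=False
            )
            assert find_tandem(cand, ref, cfg) is None

    def test_distant_duplication_is_not_tandem(self, ref, cfg):
        # insert matches a window 50 bp away from the insertion point
        insert = ref.sequence[80:101]
        cand = InsertCandidate(insert, ref_pos=150, read_offset=100, trailing=False)
        assert find_tandem(cand, ref, cfg) is None

    def test_mismatch_tolerance_is_bounded(self, ref, cfg):
        """No call ever comes from a window below the identity floor."""
        rng = random.Random(32)
        p, L = 150, 30
        max_mm = int(cfg.tandem_max_mismatch_fraction * L)
        within = mutate(rng, ref.sequence[p - L : p], max_mm)
        beyond = mutate(rng, ref.sequence[p - L : p], max_mm + 1)
        ok = find_tandem(
            InsertCandidate(within, ref_pos=p, read_offset=100, trailing=False),
            ref, cfg,
        )
        assert ok is not None and ok.mismatches_in_tandem <= max_mm
        assert (
            find_tandem(
                InsertCandidate(beyond, ref_pos=p, read_offset=100, trailing=False),
                ref, cfg,
            )
            is None
        )


class TestTrailingLengthEstimate:
    @pytest.mark.parametrize("L,dup_start", [(126, 24), (198, 22), (150, 60)])
    def test_estimate_within_3bp(self, ref, cfg, L, dup_start):
        allele = make_itd_allele(ref, ITDSpec(dup_start, L))
        read = allele[:250]
        (call,) = _detect(read, ref, cfg)
        assert call.insert.trailing and not call.exact_length
        assert abs(call.length_estimate - L) <= 3

    def test_offset_rule_on_constructed_overhang(self, ref, cfg):
        # sequenced portion matches a window exactly L bp upstream of ref_pos
        L, k, p = 126, 40, 150
        cand = InsertCandidate(
            ref.sequence[p - L : p - L + k],
            ref_pos=p, read_offset=210, trailing=True, side="right",
        )
        estimate, exact = estimate_trailing_length(cand, ref, cfg)
        assert (estimate, exact) == (L, False)

    def test_estimate_requires_a_matching_window(self, ref, cfg):
        rng = random.Random(33)
        cand = InsertCandidate(
            random_dna(rng, 40), ref_pos=150, read_offset=210,
            trailing=True, side="right",
        )
        with pytest.raises(ValueError):
            estimate_trailing_length(cand, ref, cfg)

    def test_non_trailing_candidate_rejected(self, ref, cfg):
        cand = InsertCandidate("ACGTACGT", ref_pos=150, read_offset=100, trailing=False)
        with pytest.raises(ValueError):
            estimate_trailing_length(cand, ref, cfg)


class TestRoundTrip:
    @pytest.mark.parametrize("L", [6, 10, 21, 40, 60, 90])
    @pytest.mark.parametrize("site", [120, 150, 200])
    def test_interior_duplications_recovered_exactly(self, ref, cfg, L, site):
        spec = ITDSpec(site - L, L)
        allele = make_itd_allele(ref, spec)
        # position the read so both junctions keep generous anchors
        start = site - (L + 20)
        read = allele[start : start + 250]
        (call,) = _detect(read, ref, cfg)
        assert call.length_estimate == L
        assert call.exact_length and not call.insert.trailing
        # tandem repeats make the junction ambiguous up to slippage, but the
        # called duplication must reconstruct the simulated allele exactly
        p = call.insert.ref_pos
        rebuilt = ref.sequence[:p] + call.insert.sequence + ref.sequence[p:]
        assert rebuilt == allele
        assert abs(p - spec.insertion_site) <= L + 3

    def test_wild_type_reads_never_yield_calls(self, ref, cfg):
        for start in (0, 100, 350):
            read = ref.sequence[start : start + 250]
            assert _detect(read, ref, cfg) == []
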
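"""Unit and property tests for the S-IR detection engine."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirscan.engine import (IRHit, IRParams, arm_mismatches, brute_force_irs,
                            find_irs, reverse_complement)
from sirscan.errors import ValidationError
from sirscan.seqio import GenomeRecord


@pytest.mark.parametrize("seq,expected", [
    ("ACGT", "ACGT"),                 # self-complementary
    ("AAATTC", "GAATTT"),
    ("AGAGCTCGGATCGAATCGGTAT", "ATACCGATTCGATCCGAGCTCT"),
    ("N", "N"),
    ("", ""),
])
def test_reverse_complement(seq, expected):
    assert reverse_complement(seq) == expected


@pytest.mark.parametrize("seq,mm", [
    ("AAATTCGAATTT", 0),
    ("AAATTCGACTTT", 1),   # one internal substitution in the right arm
    ("AANTTCGAATTT", 1),   # N never pairs
])
def test_arm_mismatches(seq, mm):
    assert arm_mismatches(seq, 0, 6, 0) == mm


def test_arm_mismatches_out_of_bounds():
    with pytest.raises(ValidationError):
        arm_mismatches("ACGT", 0, 6, 0)


def test_find_irs_perfect_palindrome():
    hits = find_irs(GenomeRecord("g", "AAATTCGAATTT"))
    assert hits == [IRHit("g", 0, 6, 0, 0, "AAATTC")]


def test_find_irs_with_spacer():
    hits = find_irs(GenomeRecord("g", "AAATTC" + "GCA" + "GAATTT"))
    assert hits == [IRHit("g", 0, 6, 3, 0, "AAATTC")]


def test_find_irs_empty_sequence():
    assert find_irs(GenomeRecord("g", "")) == []
    assert brute_force_irs(GenomeRecord("g", "")) == []


@pytest.mark.parametrize("arm", [
    "AGAGCTCGGATCGAATCGGTAT",          # 22 nt
    "AAATTCTTTTATTTTAGATAGAAGAAA",     # 27 nt
    "ATAAAAGAAAGAAGA",                 # 15 nt
])
def test_planted_arm_construct_max_length(arm):
    """An arm + its reverse complement between all-C flanks is detected
    with the arm's exact length as the maximum: the C|C flank pairing is
    a mismatch at both terminals, so no wider arm is admissible."""
    seq = "C" * 50 + arm + reverse_complement(arm) + "C" * 128
    hits = find_irs(GenomeRecord("t", seq))
    assert max(h.arm_len for h in hits) == len(arm)


def _hit_invariants(hits, record, params):
    for h in hits:
        assert params.min_arm <= h.arm_len <= params.max_arm
        assert 0 <= h.spacer_len <= params.max_spacer
        assert h.mismatches <= params.max_mismatch
        assert 0 <= h.left_start and h.outer_end <= record.length
        assert h.left_arm_seq == record.seq[h.left_start:
                                            h.left_start + h.arm_len]
        # both terminal pairs are exact Watson–Crick matches
        assert arm_mismatches(record.seq, h.left_start, 1,
                              h.spacer_len + 2 * (h.arm_len - 1)) == 0
        inner = h.left_start + h.arm_len - 1
        assert arm_mismatches(record.seq, inner, 1, h.spacer_len) == 0
    assert hits == sorted(hits, key=lambda h: (h.left_start, h.spacer_len))


@pytest.mark.parametrize("seed,gc", [(s, gc) for s in range(8)
                                     for gc in (0.2, 0.37, 0.5)])
def test_oracle_equivalence_random(make_genome, default_params, seed, gc):
    rec = make_genome(seed, 600, gc)
    fast = find_irs(rec, default_params)
    assert fast == brute_force_irs(rec, default_params)
    _hit_invariants(fast, rec, default_params)


@given(seq=st.text(alphabet="ACGTN", max_size=120),
       spacer=st.integers(0, 3), mm=st.integers(0, 2))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_oracle_equivalence_hypothesis(seq, spacer, mm):
    params = IRParams(min_arm=4, max_arm=20, max_spacer=spacer,
                      max_mismatch=mm)
    rec = GenomeRecord("h", seq)
    assert find_irs(rec, params) == brute_force_irs(rec, params)


def test_strand_symmetry(make_genome, default_params):
    """Hits on the reverse complement are the mirror image of the hits
    on the forward strand with arm/spacer/mismatches preserved."""
    rec = make_genome(5, 1500)
    fwd = find_irs(rec, default_params)
    rev = find_irs(GenomeRecord(rec.id, reverse_complement(rec.seq)),
                   default_params)
    n = rec.length
    mirrored = {(n - h.outer_end, h.arm_len, h.spacer_len, h.mismatches)
                for h in fwd}
    assert {(h.left_start, h.arm_len, h.spacer_len, h.mismatches)
            for h in rev} == mirrored


def test_mismatch_budget_monotonic_coverage(make_genome):
    """Raising the budget from 0 to 1 never shrinks covered positions."""
    rec = make_genome(17, 2000)
    def coverage(budget):
        hits = find_irs(rec, IRParams(max_mismatch=budget))
        cov = set()
        for h in hits:
            cov.update(range(h.left_start, h.outer_end))
        return cov
    assert coverage(0) <= coverage(1)


def test_hits_are_maximal(make_genome, default_params):
    """Extending both arms of any reported hit outward by one base
    violates bounds, the terminal-match rule, the mismatch budget, or
    the arm cap."""
    rec = make_genome(23, 1200)
    seq, p = rec.seq, default_params
    for h in find_irs(rec, p):
        wider_start = h.left_start - 1
        wider_arm = h.arm_len + 1
        if wider_arm > p.max_arm:
            continue
        if wider_start < 0 or h.outer_end + 1 > len(seq):
            continue
        mm = arm_mismatches(seq, wider_start, wider_arm, h.spacer_len)
        outer_ok = arm_mismatches(
            seq, wider_start, 1, h.spacer_len + 2 * (wider_arm - 1)) == 0
        assert mm > p.max_mismatch or not outer_ok


def test_overlapping_distinct_spans_all_kept():
    """A doubled palindrome yields overlapping hits around different
    centers; all distinct outer spans are kept and spans are unique."""
    unit = "AAATTCGAATTT"
    rec = GenomeRecord("g", unit + unit)
    hits = find_irs(rec)
    spans = {h.span for h in hits}
    assert {(0, 12), (12, 24), (0, 24)} <= spans  # copies + bridging arm-12
    assert len(spans) == len(hits)
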
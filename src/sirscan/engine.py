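"""Detection of short inverted repeats (S-IRs).

An S-IR is a pair of arms, the right arm the reverse complement of the
left up to an allowed mismatch budget, separated by a short spacer. In
this package "S-IR length" always means ARM length in bp, never the
total span.

Conventions (fixed throughout the package):

* Both terminal base pairs of the arms — the innermost pair flanking the
  spacer and the outermost pair — must be exact Watson–Crick matches;
  any allowed mismatch is internal. Without this rule every perfect
  arm-k hit would trivially extend to k+1 and reported lengths would be
  ill-defined.
* N never pairs with anything (it always counts as a mismatch).
* Candidates are generated per center (gap position × spacer length),
  arms extended outward as far as the mismatch budget and terminal rule
  allow, capped at ``max_arm``. Among hits sharing an identical outer
  span only the one with the largest arm is kept (ties: fewer
  mismatches, then smaller spacer). Hits with distinct outer spans are
  all kept, even when overlapping or nested around different centers.
* Each physical IR is counted once, not once per strand — the structure
  is strand-symmetric.

:func:`find_irs` is the production scanner (vectorised over centers);
:func:`brute_force_irs` enumerates every (left_start, arm, spacer)
triple directly and exists purely as an independent oracle for small
sequences.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .seqio import GenomeRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# Base codes such that two bases pair iff their codes sum to 3 (N=4 never pairs).
_CODE = np.full(256, 4, dtype=np.int8)
for _b, _c in zip(b"ACGT", (0, 1, 2, 3)):
    _CODE[_b] = _c


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IRParams:
    """Scan parameters: arm length range, spacer range, mismatch budget."""
    min_arm: int = 6
    max_arm: int = 60
    max_spacer: int = 10
    max_mismatch: int = 1

    def __post_init__(self):
        if not (0 < self.min_arm <= self.max_arm):
            raise ValidationError("require 0 < min_arm <= max_arm")
        if self.max_spacer < 0 or self.max_mismatch < 0:
            raise ValidationError("max_spacer and max_mismatch must be >= 0")


@dataclass(frozen=True)
class IRHit:
    """One maximal inverted repeat.

    ``left_start`` is the 0-based start of the left arm; the outer span
    is ``[left_start, left_start + 2*arm_len + spacer_len)``.
    """
    genome_id: str
    left_start: int
    arm_len: int
    spacer_len: int
    mismatches: int
    left_arm_seq: str

    @property
    def outer_end(self) -> int:
        return self.left_start + 2 * self.arm_len + self.spacer_len

    @property
    def span(self) -> tuple[int, int]:
        return self.left_start, self.outer_end


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def arm_mismatches(seq: str, left_start: int, arm_len: int,
                   spacer_len: int) -> int:
    """Count mismatched arm pairings for a putative IR placement.

    Position i of the left arm (0-based from ``left_start``) pairs with
    position ``left_start + 2*arm_len + spacer_len - 1 - i``; a pairing
    involving N is always a mismatch.
    """
    outer_end = left_start + 2 * arm_len + spacer_len
    if left_start < 0 or outer_end > len(seq):
        raise ValidationError("IR span out of sequence bounds")
    code = _CODE
    mm = 0
    for i in range(arm_len):
        a = code[ord(seq[left_start + i])]
        b = code[ord(seq[outer_end - 1 - i])]
        if a + b != 3:
            mm += 1
    return int(mm)


def find_irs(record: GenomeRecord, params: IRParams = IRParams()
             ) -> list[IRHit]:
    """Find all maximal S-IRs in a genome under *params*.

    Vectorised over centers: for every spacer length the match status of
    the i-th outward arm pairing is computed for all gap positions at
    once, cumulative mismatch counts give the largest admissible arm per
    center, and span-level deduplication is applied at the end. Returns
    hits sorted by (left_start, spacer_len, arm_len).
    """
    seq = record.seq
    n = len(seq)
    if n == 0:
        return []
    code = _codes(seq)
    min_arm, max_arm = params.min_arm, params.max_arm
    budget = params.max_mismatch

    best: dict[tuple[int, int], tuple[int, int, int]] = {}
    # best[(left_start, outer_end)] = (arm, mm, spacer), keep max arm /
    # fewer mm / smaller spacer
    arms = np.arange(1, max_arm + 1)

    for s in range(params.max_spacer + 1):
        # pair i at gap position g: left l = g-1-i, right r = g+s+i
        # match[i, g] True iff both in bounds and Watson–Crick paired
        match = np.zeros((max_arm, n + 1), dtype=bool)
        for i in range(max_arm):
            lo, hi = i + 1, n - s - i  # admissible g range (hi exclusive)
            if lo >= hi:
                break
            match[i, lo:hi] = (code[lo - 1 - i:hi - 1 - i]
                               + code[lo + s + i:hi + s + i]) == 3
        mism = np.cumsum(~match, axis=0)
        # arm L valid: terminal pairs (i=0 and i=L-1) match, mismatches ≤ budget
        valid = match & match[0] & (mism <= budget)
        best_arm = np.max(np.where(valid, arms[:, None], 0), axis=0)
        for g in np.nonzero(best_arm >= min_arm)[0]:
            arm = int(best_arm[g])
            mm = int(mism[arm - 1, g])
            left = int(g) - arm
            key = (left, left + 2 * arm + s)
            cand = (arm, -mm, -s)
            prev = best.get(key)
            if prev is None or cand > (prev[0], -prev[1], -prev[2]):
                best[key] = (arm, mm, s)

    hits = [IRHit(genome_id=record.id, left_start=left, arm_len=arm,
                  spacer_len=spacer, mismatches=mm,
                  left_arm_seq=seq[left:left + arm])
            for (left, _), (arm, mm, spacer) in best.items()]
    hits.sort(key=lambda h: (h.left_start, h.spacer_len, h.arm_len))
    return hits


def brute_force_irs(record: GenomeRecord, params: IRParams = IRParams()
                    ) -> list[IRHit]:
    """Exhaustive oracle: test every (left_start, arm, spacer) triple.

    Each triple is checked independently against the terminal-match rule
    and the mismatch budget, then the per-center maximality and span
    deduplication rules are applied. Intended for sequences up to a few
    kbp; output equals :func:`find_irs`.
    """
    seq = record.seq
    n = len(seq)
    code = [int(_CODE[ord(c)]) for c in seq]
    min_arm, max_arm = params.min_arm, params.max_arm
    budget = params.max_mismatch

    per_center: dict[tuple[int, int], tuple[int, int]] = {}  # (g,s) -> (arm, mm)
    for g in range(n + 1):
        for s in range(params.max_spacer + 1):
            li, ri = g - 1, g + s
            if li < 0 or ri >= n or code[li] + code[ri] != 3:
                continue  # innermost terminal pair must match for any arm
            for arm in range(min_arm, max_arm + 1):
                lo, hi = g - arm, g + s + arm
                if lo < 0 or hi > n:
                    break
                if code[lo] + code[hi - 1] != 3:
                    continue  # outermost terminal pair must match
                mm = 0
                for i in range(1, arm - 1):
                    if code[g - 1 - i] + code[ri + i] != 3:
                        mm += 1
                        if mm > budget:
                            break
                if mm > budget:
                    continue
                prev = per_center.get((g, s))
                if prev is None or arm > prev[0]:
                    per_center[(g, s)] = (arm, mm)

    best: dict[tuple[int, int], tuple[int, int, int]] = {}
    for (g, s), (arm, mm) in per_center.items():
        left = g - arm
        key = (left, left + 2 * arm + s)
        cand = (arm, -mm, -s)
        prev = best.get(key)
        if prev is None or cand > (prev[0], -prev[1], -prev[2]):
            best[key] = (arm, mm, s)

    hits = [IRHit(genome_id=record.id, left_start=left, arm_len=arm,
                  spacer_len=spacer, mismatches=mm,
                  left_arm_seq=seq[left:left + arm])
            for (left, _), (arm, mm, spacer) in best.items()]
    hits.sort(key=lambda h: (h.left_start, h.spacer_len, h.arm_len))
    return hits


# ---------------------------------------------------------------------------
# Hit list writers
# ---------------------------------------------------------------------------

HIT_TSV_COLUMNS = ("genome_id", "left_start", "arm_len", "spacer_len",
                   "mismatches", "left_arm_seq")


def write_hits_tsv(hits: Iterable[IRHit], path: str | Path,
                   header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.left_start}\t{h.arm_len}\t"
                     f"{h.spacer_len}\t{h.mismatches}\t{h.left_arm_seq}\n")


def read_hits_tsv(path: str | Path) -> list[IRHit]:
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") \
                or line.startswith("genome_id\t"):
            continue
        gid, left, arm, spacer, mm, arm_seq = line.split("\t")
        hits.append(IRHit(genome_id=gid, left_start=int(left),
                          arm_len=int(arm), spacer_len=int(spacer),
                          mismatches=int(mm), left_arm_seq=arm_seq))
    return hits


def write_hits_bed(hits: Iterable[IRHit], path: str | Path) -> None:
    """BED6 over the outer span; name arm:spacer:mismatch, score arm length."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.left_start}\t{h.outer_end}\t"
                     f"{h.arm_len}:{h.spacer_len}:{h.mismatches}\t"
                     f"{h.arm_len}\t.\n")
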
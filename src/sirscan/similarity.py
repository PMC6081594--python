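"""Ranking and Levenshtein grouping of abundant S-IR arm sequences.

The sequence attributed to a hit is its left arm read 5'→3'; the right
arm is the (near-)reverse-complement and is not tallied separately.
"Present N times" tallies hit occurrences pooled over all genomes, not
the number of genomes containing the arm. Distance comparisons are
restricted to arms of equal length, though insertions and deletions are
still allowed inside the metric itself.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import edlib
import pandas as pd

from .errors import ValidationError
from .engine import IRHit


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class SimilarityGroup:
    """Arms within a Levenshtein radius of a representative sequence."""
    representative: str
    exact_count: int
    near_count: int
    members: tuple[tuple[str, int], ...]


def rank_arms(hits: Sequence[IRHit], arm_len: int,
              top_k: int | None = None) -> list[tuple[str, int]]:
    """Most frequent identical left-arm sequences of a given arm length.

    Sorted by descending count, ties broken lexicographically; the top
    *top_k* entries are returned (all when None).
    """
    counter = Counter(h.left_arm_seq for h in hits if h.arm_len == arm_len)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k is not None else ranked


def near_group(hits: Sequence[IRHit], arm_len: int, seed_seq: str,
               max_dist: int = 2) -> SimilarityGroup:
    """Group all arms of *arm_len* within *max_dist* edits of *seed_seq*."""
    if len(seed_seq) != arm_len:
        raise ValidationError(
            f"seed sequence length {len(seed_seq)} != arm_len {arm_len}")
    counter = Counter(h.left_arm_seq for h in hits if h.arm_len == arm_len)
    members = []
    exact = 0
    near = 0
    for seq, count in sorted(counter.items()):
        d = levenshtein(seq, seed_seq)
        if d <= max_dist:
            members.append((seq, count))
            near += count
            if seq == seed_seq:
                exact = count
    return SimilarityGroup(representative=seed_seq, exact_count=exact,
                           near_count=near, members=tuple(members))


def similarity_table(hits: Sequence[IRHit], arm_lengths: Sequence[int],
                     top_k: int = 5, max_dist: int = 2) -> pd.DataFrame:
    """Per arm length: top-ranked arms with exact and near (<= d) counts."""
    rows = []
    for L in arm_lengths:
        for rank, (seq, count) in enumerate(rank_arms(hits, L, top_k), 1):
            grp = near_group(hits, L, seq, max_dist=max_dist)
            rows.append({"arm_len": L, "rank": rank, "sequence": seq,
                         "exact_count": count,
                         f"near_count_d{max_dist}": grp.near_count})
    return pd.DataFrame(rows)
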
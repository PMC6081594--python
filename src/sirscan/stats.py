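"""Per-genome and per-group S-IR frequency statistics.

Frequencies are reported per 1000 bp. Length classes follow the
convention used throughout the package: "8+", "10+", "12+" mean arm
length >= 8/10/12 bp, and "all" is every hit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .engine import IRHit
from .seqio import GenomeRecord

LENGTH_CLASSES = ("all", "8+", "10+", "12+")
CLASS_THRESHOLDS = {"all": 0, "8+": 8, "10+": 10, "12+": 12}


def class_of(arm_len: int) -> list[str]:
    return [c for c, t in CLASS_THRESHOLDS.items() if arm_len >= t]


@dataclass
class LengthProfile:
    """S-IR counts and per-kbp frequencies by arm length for one owner.

    Owner is either a genome id or a group label; ``seq_bp`` is the
    owner's total sequence length (pooled over genomes for a group).
    """
    owner: str
    counts: dict[int, int]
    seq_bp: int
    min_arm: int = 6
    max_arm: int = 60

    def __post_init__(self):
        if self.seq_bp <= 0:
            raise ValidationError(f"{self.owner}: seq_bp must be positive")
        full = {L: 0 for L in range(self.min_arm, self.max_arm + 1)}
        full.update(self.counts)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freq_per_kbp(self) -> dict[int, float]:
        return {L: 1000.0 * c / self.seq_bp for L, c in self.counts.items()}

    @property
    def agg_counts(self) -> dict[str, int]:
        return {cls: sum(c for L, c in self.counts.items() if L >= thr)
                for cls, thr in CLASS_THRESHOLDS.items()}

    @property
    def over30(self) -> int:
        return sum(c for L, c in self.counts.items() if L > 30)

    @property
    def max_arm_present(self) -> int:
        """Largest arm length with at least one hit (0 when empty)."""
        present = [L for L, c in self.counts.items() if c > 0]
        return max(present) if present else 0

    def total_freq_per_kbp(self) -> float:
        return 1000.0 * self.total / self.seq_bp


@dataclass(frozen=True)
class GroupSummary:
    """Table-2-style summary for one group of genomes.

    ``mean_freq`` is the unweighted arithmetic mean of per-genome
    S-IR/kbp rates; ``pooled_freq`` is pooled counts over pooled bp —
    the two differ when genome sizes differ. ``longest_for_half`` is the
    largest arm length L such that at least 50% of the group's genomes
    contain a hit with arm length >= L.
    """
    group: str
    n_seq: int
    median_size: float
    min_seq: tuple[str, int]
    max_seq: tuple[str, int]
    mean_freq: float
    pooled_freq: float
    freq_range: tuple[float, float]
    longest_for_half: int


def profile_genome(hits: Sequence[IRHit], record: GenomeRecord,
                   min_arm: int = 6, max_arm: int = 60) -> LengthProfile:
    """Tally one genome's hits into a :class:`LengthProfile`."""
    if record.length == 0:
        raise ValidationError(f"{record.id}: empty sequence")
    for h in hits:
        if h.genome_id != record.id:
            raise ValidationError(
                f"hit on {h.genome_id} passed with record {record.id}")
    counts: dict[int, int] = {}
    for h in hits:
        counts[h.arm_len] = counts.get(h.arm_len, 0) + 1
    return LengthProfile(owner=record.id, counts=counts, seq_bp=record.length,
                         min_arm=min_arm, max_arm=max_arm)


def longest_for_half(per_genome_maxima: Sequence[int]) -> int:
    """Largest L reached by the longest S-IR of at least 50% of genomes.

    Equals the upper median of per-genome maximum arm lengths (a genome
    with no hits contributes 0).
    """
    if not per_genome_maxima:
        raise ValidationError("empty group")
    s = sorted(per_genome_maxima)
    return s[len(s) // 2]


def aggregate_group(profiles: Sequence[LengthProfile],
                    records: Sequence[GenomeRecord],
                    group: str) -> tuple[LengthProfile, GroupSummary]:
    """Pool per-genome profiles into a group profile plus a summary row."""
    if not profiles:
        raise ValidationError(f"group {group!r} has no genomes")
    by_id = {r.id: r for r in records}
    missing = [p.owner for p in profiles if p.owner not in by_id]
    if missing:
        raise ValidationError(f"no GenomeRecord for profile(s) {missing}")

    counts: dict[int, int] = {}
    for p in profiles:
        for L, c in p.counts.items():
            counts[L] = counts.get(L, 0) + c
    seq_bp = sum(p.seq_bp for p in profiles)
    pooled = LengthProfile(owner=group, counts=counts, seq_bp=seq_bp,
                           min_arm=profiles[0].min_arm,
                           max_arm=profiles[0].max_arm)

    sizes = [(p.owner, by_id[p.owner].length) for p in profiles]
    freqs = [p.total_freq_per_kbp() for p in profiles]
    summary = GroupSummary(
        group=group,
        n_seq=len(profiles),
        median_size=float(np.median([s for _, s in sizes])),
        min_seq=min(sizes, key=lambda t: t[1]),
        max_seq=max(sizes, key=lambda t: t[1]),
        mean_freq=float(np.mean(freqs)),
        pooled_freq=pooled.total_freq_per_kbp(),
        freq_range=(min(freqs), max(freqs)),
        longest_for_half=longest_for_half(
            [p.max_arm_present for p in profiles]),
    )
    return pooled, summary


def table1_report(profiles: Sequence[LengthProfile]) -> pd.DataFrame:
    """Dataset-wide counts and per-kbp frequencies by arm length.

    One row per arm length 6..30 plus a pooled ">30" row; frequencies
    use the pooled sequence length of all profiles.
    """
    if not profiles:
        raise ValidationError("no profiles")
    seq_bp = sum(p.seq_bp for p in profiles)
    counts: dict[int, int] = {}
    for p in profiles:
        for L, c in p.counts.items():
            counts[L] = counts.get(L, 0) + c
    rows = []
    for L in range(6, 31):
        c = counts.get(L, 0)
        rows.append({"ir_size": str(L), "count": c,
                     "freq_per_kbp": 1000.0 * c / seq_bp})
    over = sum(c for L, c in counts.items() if L > 30)
    rows.append({"ir_size": ">30", "count": over,
                 "freq_per_kbp": 1000.0 * over / seq_bp})
    return pd.DataFrame(rows)


def profile_table(profiles: Sequence[LengthProfile]) -> pd.DataFrame:
    """Long-form per-owner table: owner, arm_len, count, freq_per_kbp."""
    rows = []
    for p in profiles:
        f = p.freq_per_kbp
        for L in sorted(p.counts):
            rows.append({"owner": p.owner, "arm_len": L,
                         "count": p.counts[L], "freq_per_kbp": f[L]})
    return pd.DataFrame(rows)


def group_summary_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({
            "group": s.group, "n_seq": s.n_seq,
            "median_size_bp": s.median_size,
            "shortest_seq": s.min_seq[0], "shortest_bp": s.min_seq[1],
            "longest_seq": s.max_seq[0], "longest_bp": s.max_seq[1],
            "mean_freq_per_kbp": s.mean_freq,
            "pooled_freq_per_kbp": s.pooled_freq,
            "freq_min": s.freq_range[0], "freq_max": s.freq_range[1],
            "longest_for_half_bp": s.longest_for_half,
        })
    return pd.DataFrame(rows)
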
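"""Synthetic annotated genomes with planted inverted repeats.

The generator emulates AT-rich plastid-like genomes: i.i.d. background
residues at a configurable GC fraction (default 0.37), a layout of
annotated features (gene, CDS, tRNA, rRNA, exon, intron, stem_loop,
repeat_region, regulatory, misc_feature), and inverted repeats planted
at controlled density per region — elevated inside stem_loop features
and immediately before repeat_region features, depleted inside rRNA —
so every downstream stage can be tested against exact ground truth.

A planted IR replaces a substring with ``arm + spacer + revcomp(arm)``;
requested mismatches are applied to the right arm at internal
positions. Spacer bases are drawn from {A,C}: no Watson–Crick pair can
form between two bases of that alphabet, so no wider-armed candidate
sharing the planted outer span can exist and the planted arm length is
unambiguous. For recovery tests the locus window (planted span plus a
2 bp margin on each side) can additionally be *screened*: rewritten
with {A,C} residues, which provably contain no inverted repeat — the
generator still verifies this with the exhaustive oracle.

All randomness flows through one ``numpy`` generator per call; the same
seed reproduces byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .engine import (IRHit, IRParams, brute_force_irs, find_irs,
                     reverse_complement, write_hits_tsv)
from .seqio import (Feature, GenomeRecord, write_fasta, write_feature_table,
                    write_manifest)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def gen_background(length: int, gc: float = 0.37,
                   seed: int | np.random.Generator = 0) -> GenomeRecord:
    """I.i.d. random genome with P(G)+P(C) = gc; deterministic per seed."""
    if length <= 0:
        raise ValidationError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValidationError("gc must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
    return GenomeRecord(id=f"synth{seed}" if isinstance(seed, int) else "synth",
                        seq=seq)


@dataclass(frozen=True)
class PlantSpec:
    """One IR to plant: arm (explicit or drawn), spacer, mismatches, locus."""
    locus: int
    arm_seq: str | None = None
    arm_len: int | None = None
    spacer_len: int = 0
    mismatch_positions: tuple[int, ...] = ()
    genome_id: str | None = None

    def resolved_arm(self, rng: np.random.Generator) -> str:
        if self.arm_seq is not None:
            return self.arm_seq
        if self.arm_len is None:
            raise ValidationError("PlantSpec needs arm_seq or arm_len")
        return rng.choice(_BASES, size=self.arm_len).tobytes().decode("ascii")


def _build_construct(arm: str, spacer_len: int,
                     mismatch_positions: Sequence[int],
                     rng: np.random.Generator) -> str:
    a = len(arm)
    if not 6 <= a <= 60:
        raise ValidationError(f"arm length {a} outside [6, 60]")
    if not 0 <= spacer_len <= 10:
        raise ValidationError(f"spacer length {spacer_len} outside [0, 10]")
    for j in mismatch_positions:
        if not 0 < j < a - 1:
            raise ValidationError(
                f"mismatch position {j} not internal for arm length {a}")
    spacer = rng.choice(np.frombuffer(b"AC", dtype="S1"),
                        size=spacer_len).tobytes().decode("ascii")
    right = list(reverse_complement(arm))
    for j in mismatch_positions:
        right[a - 1 - j] = arm[j]  # a base never pairs with itself
    return arm + spacer + "".join(right)


def plant(record: GenomeRecord, spec: PlantSpec,
          existing_spans: Sequence[tuple[int, int]] = (),
          rng: np.random.Generator | None = None
          ) -> tuple[GenomeRecord, IRHit]:
    """Plant one IR into *record*, returning the new record and the
    expected maximal hit.

    Raises when the construct overlaps a span in *existing_spans* or
    does not fit the sequence.
    """
    rng = rng or np.random.default_rng(0)
    arm = spec.resolved_arm(rng)
    construct = _build_construct(arm, spec.spacer_len,
                                 spec.mismatch_positions, rng)
    lo, hi = spec.locus, spec.locus + len(construct)
    if lo < 0 or hi > record.length:
        raise ValidationError(f"plant [{lo},{hi}) outside genome")
    for a, b in existing_spans:
        if lo < b and hi > a:
            raise ValidationError(
                f"plant [{lo},{hi}) overlaps existing plant [{a},{b})")
    seq = record.seq[:lo] + construct + record.seq[hi:]
    hit = IRHit(genome_id=spec.genome_id or record.id, left_start=lo,
                arm_len=len(arm), spacer_len=spec.spacer_len,
                mismatches=len(spec.mismatch_positions), left_arm_seq=arm)
    return GenomeRecord(id=record.id, seq=seq, group=record.group), hit


def screen_window(seq_buf: bytearray, lo: int, hi: int,
                  rng: np.random.Generator,
                  verify: bool = True) -> None:
    """Rewrite ``[lo, hi)`` with {A,C} residues, which cannot form any
    Watson–Crick pair and hence contain no inverted repeat; optionally
    verify the window is IR-free with the exhaustive oracle."""
    window = rng.choice(np.frombuffer(b"AC", dtype="S1"),
                        size=hi - lo).tobytes()
    seq_buf[lo:hi] = window
    if verify:
        probe = GenomeRecord(id="screen", seq=window.decode("ascii"))
        assert brute_force_irs(probe) == [], "screened window not IR-free"


def plant_screened_set(length: int, n_plants: int, seed: int,
                       gc: float = 0.37,
                       arm_range: tuple[int, int] = (6, 60),
                       spacer_range: tuple[int, int] = (0, 10),
                       mismatch_prob: float = 0.5, genome_id: str = "recov"
                       ) -> tuple[GenomeRecord, list[IRHit]]:
    """Background genome with *n_plants* IRs at screened, IR-free loci.

    Each planted span (plus 2 bp margins) is rewritten to the pair-free
    {A,C} alphabet before planting, so the detector must recover every
    plant at exactly its arm length and spacer. Used by recovery tests.
    """
    rng = np.random.default_rng(seed)
    rec = gen_background(length, gc, rng)
    buf = bytearray(rec.seq, "ascii")
    placed: list[tuple[int, int]] = []
    truth: list[IRHit] = []
    for _ in range(n_plants):
        arm_len = int(rng.integers(arm_range[0], arm_range[1] + 1))
        spacer = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
        mm_pos: tuple[int, ...] = ()
        if arm_len >= 3 and rng.random() < mismatch_prob:
            mm_pos = (int(rng.integers(1, arm_len - 1)),)
        span = 2 * arm_len + spacer
        win = span + 4  # 2 bp screened margin each side
        start = _sample_free_start(length, win, placed, rng)
        if start is None:
            raise ValidationError(
                f"cannot place {n_plants} plants in {length} bp")
        placed.append((start, start + win))
        screen_window(buf, start, start + win, rng)
        arm = rng.choice(_BASES, size=arm_len).tobytes().decode("ascii")
        construct = _build_construct(arm, spacer, mm_pos, rng)
        locus = start + 2
        buf[locus:locus + span] = construct.encode("ascii")
        truth.append(IRHit(genome_id=genome_id, left_start=locus,
                           arm_len=arm_len, spacer_len=spacer,
                           mismatches=len(mm_pos), left_arm_seq=arm))
    return (GenomeRecord(id=genome_id, seq=buf.decode("ascii")),
            sorted(truth, key=lambda h: h.left_start))


def _sample_free_start(window_len: int, span: int,
                       placed: Sequence[tuple[int, int]],
                       rng: np.random.Generator,
                       lo: int = 0) -> int | None:
    """Uniformly sample a start in [lo, lo+window_len) such that
    [start, start+span) avoids every placed interval; None when full."""
    hi = lo + window_len
    segs = []
    cursor = lo
    for a, b in sorted(placed):
        end = min(a - span, hi - span)  # inclusive start range
        if end >= cursor:
            segs.append((cursor, end))
        cursor = max(cursor, b)
        if cursor > hi - span:
            break
    else:
        if hi - span >= cursor:
            segs.append((cursor, hi - span))
    weights = [e - s + 1 for s, e in segs]
    total = sum(weights)
    if total == 0:
        return None
    pick = int(rng.integers(0, total))
    for (s, e), w in zip(segs, weights):
        if pick < w:
            return s + pick
        pick -= w
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Full annotated dataset
# ---------------------------------------------------------------------------

#: (count per genome, feature length bp); chosen so a 24 kbp genome holds
#: one layout with realistic inter-feature gaps, and so the gene
#: baseline has enough features for stable enrichment estimates.
DEFAULT_LAYOUT: dict[str, tuple[int, int]] = {
    "gene": (16, 500),
    "CDS": (3, 400),
    "tRNA": (3, 80),
    "rRNA": (1, 1500),
    "exon": (3, 250),
    "intron": (2, 400),
    "stem_loop": (8, 500),
    "repeat_region": (1, 1500),
    "regulatory": (2, 150),
    "misc_feature": (2, 250),
}

#: Planted-IR density multipliers relative to the gene baseline,
#: emulating the qualitative enrichment pattern of plastid genomes:
#: strong stem-loop enrichment, moderate intron/regulatory enrichment,
#: rRNA depletion.
DEFAULT_INSIDE_MULT: dict[str, float] = {
    "stem_loop": 10.0,
    "intron": 2.4,
    "regulatory": 3.2,
    "rRNA": 0.2,
}

#: Multipliers for the 100 bp window immediately before a feature.
DEFAULT_BEFORE_MULT: dict[str, float] = {
    "repeat_region": 7.6,
}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""
    n_genomes: int = 8
    length_bp: int = 24_000
    gc_fraction: float = 0.37
    seed: int = 0
    n_groups: int = 2
    feature_layout: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LAYOUT))
    inside_mult: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INSIDE_MULT))
    before_mult: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEFORE_MULT))
    base_density_per_kbp: float = 2.0     # planted IRs/kbp at multiplier 1
    plant_arm_range: tuple[int, int] = (12, 15)
    plant_spacer_range: tuple[int, int] = (0, 2)
    mismatch_prob: float = 0.5
    before_window: int = 100
    min_gap: int = 20

    def __post_init__(self):
        if any(m < 0 for m in self.inside_mult.values()):
            raise ValidationError("density multipliers must be >= 0")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus writers for the on-disk artefacts."""
    records: list[GenomeRecord]
    features: list[Feature]
    manifest: dict[str, str]
    truth: list[IRHit]
    truth_placement: list[str]   # parallel to truth, e.g. "inside:stem_loop"
    config: SynthConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genomes.fasta",
            "features": outdir / "features.tbl",
            "manifest": outdir / "manifest.tsv",
            "truth": outdir / "ground_truth.tsv",
            "config": outdir / "synth_config.yaml",
        }
        write_fasta(self.records, paths["fasta"])
        write_feature_table(self.features, paths["features"])
        write_manifest(self.manifest, paths["manifest"])
        with open(paths["truth"], "w") as fh:
            fh.write("genome_id\tleft_start\tarm_len\tspacer_len\t"
                     "mismatches\tleft_arm_seq\tplacement\n")
            for h, where in zip(self.truth, self.truth_placement):
                fh.write(f"{h.genome_id}\t{h.left_start}\t{h.arm_len}\t"
                         f"{h.spacer_len}\t{h.mismatches}\t"
                         f"{h.left_arm_seq}\t{where}\n")
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=True)
        return paths


def _layout_genome(cfg: SynthConfig, genome_id: str,
                   rng: np.random.Generator) -> list[Feature]:
    items: list[tuple[str, int]] = []
    for ftype, (count, flen) in cfg.feature_layout.items():
        items.extend([(ftype, flen)] * count)
    order = rng.permutation(len(items))
    items = [items[i] for i in order]
    total = sum(flen for _, flen in items)
    slack = cfg.length_bp - total - cfg.min_gap * (len(items) + 1)
    if slack < 0:
        raise ValidationError(
            f"feature layout needs {total} bp plus gaps; genome is "
            f"{cfg.length_bp} bp")
    extra = rng.multinomial(slack, np.full(len(items) + 1,
                                           1.0 / (len(items) + 1)))
    feats = []
    pos = 0
    for (ftype, flen), gap in zip(items, extra):
        pos += cfg.min_gap + int(gap)
        feats.append(Feature(genome_id=genome_id, ftype=ftype,
                             start=pos, end=pos + flen,
                             strand="+" if rng.random() < 0.5 else "-"))
        pos += flen
    return feats


def gen_dataset(cfg: SynthConfig, outdir: str | Path | None = None
                ) -> SyntheticDataset:
    """Generate an annotated multi-genome dataset with planted IRs.

    Plants are placed by a Poisson process per region: inside every
    feature at ``base_density_per_kbp`` times the feature type's
    multiplier, and in the gap immediately before selected feature
    types. Placement samples uniformly over the exactly-computed free
    positions; when a region fills up, remaining draws for it are
    dropped (the ground truth records only what was actually planted).
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[GenomeRecord] = []
    features: list[Feature] = []
    truth: list[IRHit] = []
    placement: list[str] = []

    for gi in range(cfg.n_genomes):
        gid = f"synth{gi:02d}"
        rec = gen_background(cfg.length_bp, cfg.gc_fraction, rng)
        buf = bytearray(rec.seq, "ascii")
        feats = _layout_genome(cfg, gid, rng)
        features.extend(feats)
        placed: list[tuple[int, int]] = []

        tasks: list[tuple[int, int, str]] = []  # (window lo, hi, tag)
        prev_end = 0
        for f in sorted(feats, key=lambda f: f.start):
            mult = cfg.inside_mult.get(f.ftype, 1.0)
            if mult > 0:
                tasks.append((f.start + 2, f.end - 2, f"inside:{f.ftype}"))
            bmult = cfg.before_mult.get(f.ftype, 0.0)
            if bmult > 0:
                lo = max(prev_end, f.start - cfg.before_window)
                if f.start - lo > 10:
                    tasks.append((lo, f.start, f"before:{f.ftype}"))
            prev_end = f.end

        for lo, hi, tag in tasks:
            kind, ftype = tag.split(":")
            mult = (cfg.inside_mult.get(ftype, 1.0) if kind == "inside"
                    else cfg.before_mult[ftype])
            lam = cfg.base_density_per_kbp * mult * (hi - lo) / 1000.0
            k = int(rng.poisson(lam))
            for _ in range(k):
                arm_len = int(rng.integers(cfg.plant_arm_range[0],
                                           cfg.plant_arm_range[1] + 1))
                spacer = int(rng.integers(cfg.plant_spacer_range[0],
                                          cfg.plant_spacer_range[1] + 1))
                mm_pos: tuple[int, ...] = ()
                if rng.random() < cfg.mismatch_prob:
                    mm_pos = (int(rng.integers(1, arm_len - 1)),)
                span = 2 * arm_len + spacer
                start = _sample_free_start(hi - lo, span, placed, rng, lo=lo)
                if start is None:
                    continue  # region full; density bias is recorded truthfully
                placed.append((start, start + span))
                arm = rng.choice(_BASES, size=arm_len).tobytes().decode("ascii")
                construct = _build_construct(arm, spacer, mm_pos, rng)
                buf[start:start + span] = construct.encode("ascii")
                truth.append(IRHit(genome_id=gid, left_start=start,
                                   arm_len=arm_len, spacer_len=spacer,
                                   mismatches=len(mm_pos), left_arm_seq=arm))
                placement.append(tag)

        records.append(GenomeRecord(id=gid, seq=buf.decode("ascii")))

    manifest = {r.id: f"group{(i % cfg.n_groups) + 1}"
                for i, r in enumerate(records)}
    order = sorted(range(len(truth)),
                   key=lambda i: (truth[i].genome_id, truth[i].left_start))
    ds = SyntheticDataset(records=records, features=features,
                          manifest=manifest,
                          truth=[truth[i] for i in order],
                          truth_placement=[placement[i] for i in order],
                          config=cfg)
    if outdir is not None:
        ds.write(outdir)
    return ds
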
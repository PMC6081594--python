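"""Sequence, annotation and manifest I/O.

Reads multi-record FASTA, NCBI 5-column feature tables and GFF3, and a
two-column genome→group manifest. All coordinates are normalised to
0-based half-open intervals at the boundary; both input dialects are
1-based inclusive. Residues are uppercased and every IUPAC ambiguity
code other than N is mapped to N — an ambiguous base never supports a
Watson–Crick pair downstream, so this is the conservative choice.

Sequences are treated as linear; no wrap-around across the circular
origin is attempted.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_NORMALISE = {c: (c if c in _VALID else "N") for c in
              "ACGTNRYSWKMBDHVU".upper()}


def normalize_seq(raw: str, record_id: str = "?") -> str:
    """Uppercase and collapse non-{A,C,G,T,N} residues to N."""
    up = raw.upper()
    if set(up) <= _VALID:
        return up
    out = []
    n_mapped = 0
    for c in up:
        if c in _VALID:
            out.append(c)
        else:
            out.append("N")
            n_mapped += 1
    log.warning("%s: %d residue(s) outside {A,C,G,T,N} mapped to N",
                record_id, n_mapped)
    return "".join(out)


@dataclass(frozen=True)
class GenomeRecord:
    """One genome: identifier, normalised residues, optional group label."""
    id: str
    seq: str
    group: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Feature:
    """Annotated interval, 0-based half-open, strand in {+,-,unknown}."""
    genome_id: str
    ftype: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not self.ftype:
            raise ValidationError("feature type must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.ftype} on {self.genome_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a multi-record FASTA file into normalised :class:`GenomeRecord`s."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_seq(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path,
                width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="")
                   for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Annotations: NCBI 5-column feature table and GFF3
# ---------------------------------------------------------------------------

_FT_HEADER = re.compile(r"^>Feature\s+(?:\S+\|)?([^|\s]+)\|?\s*$")


def _looks_like_gff3(text: str) -> bool:
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            if line.startswith("##gff-version"):
                return True
            continue
        return line.count("\t") >= 7
    return False


def _convert_1based(a: int, b: int, strand_hint: str | None = None
                    ) -> tuple[int, int, str]:
    """1-based inclusive pair → (start, end, strand); reversed pair = minus."""
    if a <= b:
        return a - 1, b, strand_hint or "+"
    return b - 1, a, "-"


def _parse_feature_table(text: str, path: Path) -> list[Feature]:
    feats: list[Feature] = []
    genome = None
    current_type = None
    comp = re.compile(r"^complement\((\d+)\.\.(\d+)\)$")
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        m = _FT_HEADER.match(line)
        if m:
            genome = m.group(1)
            current_type = None
            continue
        cols = line.rstrip("\n").split("\t")
        if line.startswith("\t"):
            # qualifier line — intervals/types only, skip
            continue
        if genome is None:
            raise FormatError(f"{path}:{lineno}: interval before '>Feature' header")
        cm = comp.match(cols[0])
        if cm:
            a, b = int(cm.group(1)), int(cm.group(2))
            start, end, _ = _convert_1based(a, b)
            strand = "-"
            ftype = cols[1] if len(cols) > 1 and cols[1] else current_type
        else:
            try:
                a = int(cols[0].lstrip("<>"))
                b = int(cols[1].lstrip("<>"))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: cannot parse interval: "
                                  f"{line!r}") from exc
            start, end, strand = _convert_1based(a, b)
            ftype = cols[2] if len(cols) > 2 and cols[2] else current_type
        if ftype is None:
            raise FormatError(f"{path}:{lineno}: continuation interval "
                              "before any typed feature")
        current_type = ftype
        feats.append(Feature(genome_id=genome, ftype=ftype,
                             start=start, end=end, strand=strand))
    return feats


def _parse_gff3(text: str, path: Path) -> list[Feature]:
    feats = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 8:
            raise FormatError(f"{path}:{lineno}: GFF3 row has {len(cols)} "
                              "columns, expected ≥8")
        seqid, _, ftype, start, end, _, strand = cols[:7]
        s, e, _ = _convert_1based(int(start), int(end))
        strand = strand if strand in "+-" else "unknown"
        feats.append(Feature(genome_id=seqid, ftype=ftype,
                             start=s, end=e, strand=strand))
    return feats


def read_feature_table(path: str | Path, genome_id: str | None = None,
                       genome_length: int | None = None) -> list[Feature]:
    """Parse annotations from an NCBI 5-column feature table or GFF3 file.

    The dialect is auto-detected from content. Multi-interval (join)
    features yield one :class:`Feature` per interval. When *genome_id*
    is given only that genome's features are returned; when
    *genome_length* is also given, intervals past the genome end raise
    :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    if _looks_like_gff3(text):
        feats = _parse_gff3(text, path)
    else:
        feats = _parse_feature_table(text, path)
    if genome_id is not None:
        feats = [f for f in feats if f.genome_id == genome_id]
        if genome_length is not None:
            for f in feats:
                if f.end > genome_length:
                    raise ValidationError(
                        f"{path}: feature {f.ftype} [{f.start},{f.end}) "
                        f"exceeds genome length {genome_length} of {genome_id}")
    return feats


def write_feature_table(features: Iterable[Feature], path: str | Path) -> None:
    """Write features grouped by genome in NCBI 5-column format."""
    by_genome: dict[str, list[Feature]] = {}
    for f in features:
        by_genome.setdefault(f.genome_id, []).append(f)
    with open(path, "w") as fh:
        for genome, feats in by_genome.items():
            fh.write(f">Feature {genome}\n")
            for f in feats:
                a, b = f.start + 1, f.end
                if f.strand == "-":
                    a, b = b, a
                fh.write(f"{a}\t{b}\t{f.ftype}\n")


# ---------------------------------------------------------------------------
# Group manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a TSV mapping genome id → group label.

    An optional header row ``genome_id\\tgroup`` is tolerated. Duplicate
    genome ids are an error; an empty file yields an empty mapping.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated "
                              f"columns (genome_id, group), got {len(cols)}")
        gid, group = cols[0], cols[1]
        if lineno == 1 and gid.lower() == "genome_id":
            continue
        if gid in mapping:
            raise FormatError(f"{path}:{lineno}: duplicate genome id {gid!r}")
        mapping[gid] = group
    return mapping


def write_manifest(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgroup\n")
        for gid, group in mapping.items():
            fh.write(f"{gid}\t{group}\n")


def apply_manifest(records: Iterable[GenomeRecord],
                   mapping: Mapping[str, str]) -> list[GenomeRecord]:
    """Return records with group labels attached where the manifest has one."""
    return [GenomeRecord(id=r.id, seq=r.seq, group=mapping.get(r.id, r.group))
            for r in records]
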
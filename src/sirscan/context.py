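"""S-IR counts around annotated features and enrichment vs the gene baseline.

Each feature defines three regions in genome coordinates: ``before``
(the ``flank`` bp immediately left of the feature start), ``inside``
(the feature span) and ``after`` (the ``flank`` bp right of the feature
end). Regions are not strand-aware: "before" always means lower
coordinates. Flank regions are clipped at genome ends and the clipped
widths enter the region size. A hit is counted in every region its
outer span overlaps by at least 1 bp, so a boundary-spanning hit
contributes to two (or three) regions. Overlapping features of the same
type each contribute their own regions; region bp may double-count.

Enrichment compares each (feature type, region, length class) frequency
to the frequency inside ``gene`` features of the same length class —
genes being the most commonly annotated location, they serve as the
baseline.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import logging

import pandas as pd

from .errors import ValidationError
from .engine import IRHit
from .seqio import Feature
from .stats import LENGTH_CLASSES, CLASS_THRESHOLDS

log = logging.getLogger(__name__)

REGIONS = ("before", "inside", "after")

#: Maximum possible hit outer span under the default scan parameters
#: (2*60 + 10); used only to bound candidate searches.
_MAX_SPAN = 130


@dataclass(frozen=True)
class FeatureContextCounts:
    ftype: str
    region: str
    length_class: str
    ir_count: int
    region_bp: int

    @property
    def freq_per_kbp(self) -> float:
        if self.region_bp == 0:
            return 0.0
        return 1000.0 * self.ir_count / self.region_bp


@dataclass(frozen=True)
class EnrichmentRatio:
    ftype: str
    region: str
    length_class: str
    ratio: float


def _regions(feature: Feature, flank: int, genome_len: int
             ) -> dict[str, tuple[int, int]]:
    return {
        "before": (max(0, feature.start - flank), feature.start),
        "inside": (feature.start, feature.end),
        "after": (feature.end, min(genome_len, feature.end + flank)),
    }


def classify_hit(hit: IRHit, feature: Feature, flank: int = 100,
                 genome_length: int | None = None) -> set[str]:
    """Regions of *feature* that the hit's outer span overlaps (>= 1 bp)."""
    if hit.genome_id != feature.genome_id:
        raise ValidationError("hit and feature on different genomes")
    glen = genome_length if genome_length is not None else feature.end + flank
    out = set()
    for name, (a, b) in _regions(feature, flank, glen).items():
        if hit.left_start < b and hit.outer_end > a:
            out.add(name)
    return out


def context_counts(hits: Sequence[IRHit], features: Sequence[Feature],
                   genome_lengths: Mapping[str, int],
                   flank: int = 100) -> list[FeatureContextCounts]:
    """Count hits before/inside/after each feature type, by length class.

    ``ir_count`` tallies (hit, feature, region) classification events;
    a hit overlapping two features of the same type is counted twice.
    ``region_bp`` sums the clipped widths of that region over all
    features of the type. Feature types with zero features are absent.
    """
    hits_by_genome: dict[str, list[IRHit]] = {}
    for h in sorted(hits, key=lambda h: h.left_start):
        hits_by_genome.setdefault(h.genome_id, []).append(h)
    starts_by_genome = {g: [h.left_start for h in hs]
                        for g, hs in hits_by_genome.items()}

    counts: dict[tuple[str, str, str], int] = {}
    bp: dict[tuple[str, str], int] = {}
    for f in features:
        if f.genome_id not in genome_lengths:
            raise ValidationError(f"no genome length for {f.genome_id}")
        glen = genome_lengths[f.genome_id]
        if f.end > glen:
            raise ValidationError(
                f"feature {f.ftype} [{f.start},{f.end}) exceeds genome "
                f"length {glen} of {f.genome_id}")
        regions = _regions(f, flank, glen)
        for region, (a, b) in regions.items():
            bp[(f.ftype, region)] = bp.get((f.ftype, region), 0) + (b - a)
        ghits = hits_by_genome.get(f.genome_id, ())
        if not ghits:
            continue
        starts = starts_by_genome[f.genome_id]
        win_lo = regions["before"][0] - _MAX_SPAN
        win_hi = regions["after"][1]
        for idx in range(bisect_left(starts, win_lo), len(starts)):
            h = ghits[idx]
            if h.left_start >= win_hi:
                break
            for region, (a, b) in regions.items():
                if h.left_start < b and h.outer_end > a:
                    for cls, thr in CLASS_THRESHOLDS.items():
                        if h.arm_len >= thr:
                            key = (f.ftype, region, cls)
                            counts[key] = counts.get(key, 0) + 1

    out = []
    for (ftype, region), region_bp in sorted(bp.items()):
        for cls in LENGTH_CLASSES:
            out.append(FeatureContextCounts(
                ftype=ftype, region=region, length_class=cls,
                ir_count=counts.get((ftype, region, cls), 0),
                region_bp=region_bp))
    return out


def enrichment(context: Sequence[FeatureContextCounts],
               baseline_ftype: str = "gene",
               baseline_region: str = "inside") -> list[EnrichmentRatio]:
    """Frequency ratios of every (ftype, region, class) vs the baseline.

    Classes whose baseline frequency is zero or absent are flagged with
    a warning and omitted rather than emitted as a number.
    """
    base: dict[str, float] = {}
    for c in context:
        if c.ftype == baseline_ftype and c.region == baseline_region:
            base[c.length_class] = c.freq_per_kbp
    out = []
    skipped = set()
    for c in context:
        b = base.get(c.length_class)
        if b is None or b == 0.0:
            skipped.add(c.length_class)
            continue
        out.append(EnrichmentRatio(ftype=c.ftype, region=c.region,
                                   length_class=c.length_class,
                                   ratio=c.freq_per_kbp / b))
    for cls in sorted(skipped):
        log.warning("enrichment undefined for class %s: baseline "
                    "(%s, %s) frequency is zero or absent",
                    cls, baseline_ftype, baseline_region)
    return out


def context_table(context: Sequence[FeatureContextCounts],
                  ratios: Sequence[EnrichmentRatio] = ()) -> pd.DataFrame:
    rmap = {(r.ftype, r.region, r.length_class): r.ratio for r in ratios}
    rows = []
    for c in context:
        rows.append({
            "ftype": c.ftype, "region": c.region,
            "length_class": c.length_class, "ir_count": c.ir_count,
            "region_bp": c.region_bp, "freq_per_kbp": c.freq_per_kbp,
            "enrichment_vs_gene": rmap.get(
                (c.ftype, c.region, c.length_class), float("nan")),
        })
    return pd.DataFrame(rows)
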
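"""End-to-end pipeline stages and report writers.

Every stage is a plain function over library objects; the CLI in
:mod:`sirscan.cli` is a thin wrapper. All outputs are deterministic for
fixed inputs and parameters: floats are printed with fixed precision
and no timestamps are embedded, so reruns are byte-identical. Each
report carries a comment header echoing the parameters that produced
it, and ``run_all`` writes a machine-readable run manifest with input
hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import seqio
from .context import context_counts, context_table, enrichment
from .engine import IRHit, IRParams, find_irs, write_hits_bed, write_hits_tsv
from .errors import UserInputError, ValidationError
from .multivariate import pca, profile_matrix, to_newick, ward_cluster
from .similarity import similarity_table
from .stats import (LengthProfile, aggregate_group, group_summary_table,
                    profile_genome, profile_table, table1_report)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters and paths for one pipeline run.

    Defaults are the standard scan conditions: arms 6–60 bp, spacer
    0–10 bp, one mismatch, ±100 bp feature neighbourhoods, Levenshtein
    radius 2.
    """
    fasta: str | None = None
    features: str | None = None
    manifest: str | None = None
    outdir: str = "sirscan_out"
    min_arm: int = 6
    max_arm: int = 60
    max_spacer: int = 10
    max_mismatch: int = 1
    flank_bp: int = 100
    similarity_max_dist: int = 2
    top_k: int = 5
    pca_scale: bool = True
    seed: int = 0

    @property
    def ir_params(self) -> IRParams:
        return IRParams(min_arm=self.min_arm, max_arm=self.max_arm,
                        max_spacer=self.max_spacer,
                        max_mismatch=self.max_mismatch)

    def header_lines(self, stage: str = "scan") -> list[str]:
        """Parameter echo for report headers; only parameters that the
        stage actually consumes, so stage outputs are isolated."""
        scan = (f"min_arm={self.min_arm} max_arm={self.max_arm} "
                f"max_spacer={self.max_spacer} "
                f"max_mismatch={self.max_mismatch}")
        extra = {
            "scan": "", "stats": "",
            "context": f" flank_bp={self.flank_bp}",
            "similarity": (f" similarity_max_dist={self.similarity_max_dist}"
                           f" top_k={self.top_k}"),
            "cluster": "", "pca": f" pca_scale={self.pca_scale}",
        }[stage]
        return [f"sirscan {stage}: {scan}{extra}"]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise UserInputError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _write_df(df: pd.DataFrame, path: Path, header_lines: Sequence[str],
              float_format: str = "%.6g") -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def _load_inputs(cfg: RunConfig):
    if not cfg.fasta:
        raise UserInputError("no input FASTA configured")
    records = seqio.read_fasta(cfg.fasta)
    if cfg.manifest:
        records = seqio.apply_manifest(records,
                                       seqio.read_manifest(cfg.manifest))
    return records


def scan_records(records, params: IRParams) -> dict[str, list[IRHit]]:
    return {r.id: find_irs(r, params) for r in records}


def run_scan(cfg: RunConfig) -> dict[str, list[IRHit]]:
    """Detect S-IRs per genome; write one TSV and one BED6 per genome."""
    records = _load_inputs(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hits_by_genome = scan_records(records, cfg.ir_params)
    total_bp = sum(r.length for r in records)
    total_hits = 0
    for r in records:
        hits = hits_by_genome[r.id]
        total_hits += len(hits)
        write_hits_tsv(hits, outdir / f"{r.id}.hits.tsv",
                       header_lines=cfg.header_lines("scan"))
        write_hits_bed(hits, outdir / f"{r.id}.hits.bed")
    log.info("scanned %d genome(s), %d bp, %d S-IR hit(s)",
             len(records), total_bp, total_hits)
    return hits_by_genome


def _profiles(records, hits_by_genome, cfg: RunConfig
              ) -> list[LengthProfile]:
    return [profile_genome(hits_by_genome[r.id], r,
                           min_arm=cfg.min_arm, max_arm=cfg.max_arm)
            for r in records]


def run_stats(cfg: RunConfig, records=None, hits_by_genome=None) -> None:
    """Per-genome profiles, Table-1-style dataset table and, when a
    group manifest is available, per-group profiles and summaries."""
    records = records if records is not None else _load_inputs(cfg)
    if hits_by_genome is None:
        hits_by_genome = scan_records(records, cfg.ir_params)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = _profiles(records, hits_by_genome, cfg)
    hdr = cfg.header_lines("stats")
    _write_df(profile_table(profiles), outdir / "genome_profiles.tsv", hdr)
    _write_df(table1_report(profiles), outdir / "dataset_by_length.tsv", hdr)

    groups = sorted({r.group for r in records if r.group})
    if not groups:
        log.warning("no group manifest: group statistics skipped")
        return
    by_id = {p.owner: p for p in profiles}
    group_profiles, summaries = [], []
    for g in groups:
        members = [r for r in records if r.group == g]
        pooled, summary = aggregate_group([by_id[r.id] for r in members],
                                          members, g)
        group_profiles.append(pooled)
        summaries.append(summary)
    _write_df(profile_table(group_profiles),
              outdir / "group_profiles.tsv", hdr)
    _write_df(group_summary_table(summaries),
              outdir / "group_summary.tsv", hdr)


def run_context(cfg: RunConfig, records=None, hits_by_genome=None) -> None:
    """Before/inside/after counts per feature type plus enrichment vs gene."""
    records = records if records is not None else _load_inputs(cfg)
    if not cfg.features:
        raise UserInputError("no feature annotation configured")
    if hits_by_genome is None:
        hits_by_genome = scan_records(records, cfg.ir_params)
    lengths = {r.id: r.length for r in records}
    feats = []
    for r in records:
        feats.extend(seqio.read_feature_table(cfg.features, r.id, r.length))
    all_hits = [h for r in records for h in hits_by_genome[r.id]]
    ctx = context_counts(all_hits, feats, lengths, flank=cfg.flank_bp)
    ratios = enrichment(ctx)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_df(context_table(ctx, ratios), outdir / "feature_context.tsv",
              cfg.header_lines("context"))


def run_similarity(cfg: RunConfig, records=None, hits_by_genome=None) -> None:
    """Rank abundant arms per length and attach Levenshtein-d2 counts."""
    records = records if records is not None else _load_inputs(cfg)
    if hits_by_genome is None:
        hits_by_genome = scan_records(records, cfg.ir_params)
    all_hits = [h for r in records for h in hits_by_genome[r.id]]
    lengths = sorted({h.arm_len for h in all_hits})
    table = similarity_table(all_hits, lengths, top_k=cfg.top_k,
                             max_dist=cfg.similarity_max_dist)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_df(table, outdir / "similarity.tsv", cfg.header_lines("similarity"))


def _owner_matrix(cfg: RunConfig, records, hits_by_genome, per_group: bool):
    profiles = _profiles(records, hits_by_genome, cfg)
    if not per_group:
        return profile_matrix(profiles)
    groups = sorted({r.group for r in records if r.group})
    if not groups:
        raise UserInputError("group-level analysis needs a manifest")
    by_id = {p.owner: p for p in profiles}
    pooled = []
    for g in groups:
        members = [r for r in records if r.group == g]
        gp, _ = aggregate_group([by_id[r.id] for r in members], members, g)
        pooled.append(gp)
    return profile_matrix(pooled)


def run_cluster(cfg: RunConfig, records=None, hits_by_genome=None,
                per_group: bool = True) -> None:
    """Ward.D2 dendrogram of frequency profiles, exported as Newick."""
    records = records if records is not None else _load_inputs(cfg)
    if hits_by_genome is None:
        hits_by_genome = scan_records(records, cfg.ir_params)
    try:
        m = _owner_matrix(cfg, records, hits_by_genome, per_group)
    except UserInputError:
        log.warning("no manifest: clustering per genome instead of per group")
        m = _owner_matrix(cfg, records, hits_by_genome, False)
    dend = ward_cluster(m)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "cluster.nwk").write_text(to_newick(dend) + "\n")
    merge_df = pd.DataFrame(dend.merges, columns=["left", "right", "height"])
    _write_df(merge_df, outdir / "cluster_merges.tsv",
              cfg.header_lines("cluster"))


def run_pca(cfg: RunConfig, records=None, hits_by_genome=None) -> None:
    """PCA of per-genome frequency profiles; scores/loadings/variance TSVs."""
    records = records if records is not None else _load_inputs(cfg)
    if hits_by_genome is None:
        hits_by_genome = scan_records(records, cfg.ir_params)
    m = _owner_matrix(cfg, records, hits_by_genome, per_group=False)
    res = pca(m, scale=cfg.pca_scale)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = cfg.header_lines("pca")
    _write_df(res.scores.reset_index(names="owner"),
              outdir / "pca_scores.tsv", hdr)
    _write_df(res.loadings.reset_index(names="variable"),
              outdir / "pca_loadings.tsv", hdr)
    var_df = pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(res.explained_variance))],
        "explained_variance": res.explained_variance,
        "explained_ratio": res.explained_ratio,
    })
    _write_df(var_df, outdir / "pca_variance.tsv", hdr)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> None:
    """Full report bundle: scan, stats, context, similarity, cluster, PCA.

    Group-level steps degrade gracefully without a manifest; the context
    step is skipped (with a warning) without annotations. A run manifest
    with parameters and input hashes accompanies the bundle.
    """
    records = _load_inputs(cfg)
    hits = run_scan(cfg)
    run_stats(cfg, records, hits)
    if cfg.features:
        run_context(cfg, records, hits)
    else:
        log.warning("no feature annotation: context step skipped")
    run_similarity(cfg, records, hits)
    run_cluster(cfg, records, hits)
    run_pca(cfg, records, hits)
    params = {k: v for k, v in asdict(cfg).items() if k != "outdir"}
    manifest = {
        "parameters": params,
        "inputs": {name: {"path": p, "sha256": _sha256(p)}
                   for name, p in (("fasta", cfg.fasta),
                                   ("features", cfg.features),
                                   ("manifest", cfg.manifest)) if p},
    }
    with open(Path(cfg.outdir) / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
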
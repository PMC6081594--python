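"""Synthetic genome generator: backgrounds, planting, datasets."""
import filecmp

import numpy as np
import pytest

from sirscan.engine import IRParams, brute_force_irs, find_irs, \
    reverse_complement
from sirscan.errors import ValidationError
from sirscan.seqio import GenomeRecord
from sirscan.synth import (PlantSpec, SynthConfig, gen_background,
                           gen_dataset, plant, plant_screened_set)


def test_background_alphabet_and_gc_extremes():
    assert set(gen_background(1000, gc=0.0, seed=1).seq) <= {"A", "T"}
    assert set(gen_background(1000, gc=1.0, seed=1).seq) <= {"C", "G"}


def test_background_determinism():
    assert gen_background(500, 0.37, seed=9).seq == \
        gen_background(500, 0.37, seed=9).seq


def test_background_gc_within_binomial_bound():
    rec = gen_background(100_000, 0.37, seed=41)
    gc = sum(c in "GC" for c in rec.seq) / rec.length
    sigma = np.sqrt(0.37 * 0.63 / rec.length)
    assert abs(gc - 0.37) < 3 * sigma


def test_background_validates_inputs():
    with pytest.raises(ValidationError):
        gen_background(0, 0.37, 1)
    with pytest.raises(ValidationError):
        gen_background(100, 1.5, 1)


def test_plant_perfect_ir():
    rec = GenomeRecord("g", "C" * 300)
    out, hit = plant(rec, PlantSpec(locus=100, arm_seq="AAATTC"))
    assert (hit.left_start, hit.arm_len, hit.spacer_len,
            hit.mismatches) == (100, 6, 0, 0)
    assert out.seq[100:112] == "AAATTC" + reverse_complement("AAATTC")


def test_plant_internal_mismatch():
    rec = GenomeRecord("g", "C" * 300)
    out, hit = plant(rec, PlantSpec(locus=50, arm_seq="AAATTCGG",
                                    spacer_len=2, mismatch_positions=(3,)))
    assert hit.mismatches == 1
    # detector agrees with the expected hit exactly
    found = [h for h in find_irs(out) if h.left_start == 50]
    assert found and found[0].arm_len == 8 and found[0].spacer_len == 2 \
        and found[0].mismatches == 1


def test_plant_rejects_terminal_mismatch_and_overlap():
    rec = GenomeRecord("g", "C" * 300)
    with pytest.raises(ValidationError):
        plant(rec, PlantSpec(locus=10, arm_seq="AAATTC",
                             mismatch_positions=(0,)))
    with pytest.raises(ValidationError):
        plant(rec, PlantSpec(locus=10, arm_seq="AAATTC"),
              existing_spans=[(15, 40)])


def test_screened_recovery_exact():
    rec, truth = plant_screened_set(10_000, 20, seed=43)
    found = {(h.left_start, h.arm_len, h.spacer_len, h.mismatches)
             for h in find_irs(rec)}
    for t in truth:
        assert (t.left_start, t.arm_len, t.spacer_len,
                t.mismatches) in found


def test_screened_windows_are_ir_free():
    """The {A,C} screening alphabet admits no Watson–Crick pair, so a
    screened window contains no IR at all, even with a mismatch budget."""
    rng = np.random.default_rng(0)
    window = "".join(rng.choice(list("AC"), size=200))
    assert brute_force_irs(GenomeRecord("w", window),
                           IRParams(max_mismatch=1)) == []


def test_gen_dataset_no_planting():
    cfg = SynthConfig(n_genomes=2, seed=5, base_density_per_kbp=0.0,
                      before_mult={})
    ds = gen_dataset(cfg)
    assert ds.truth == []


def test_gen_dataset_ground_truth_consistency():
    ds = gen_dataset(SynthConfig(n_genomes=2, seed=5))
    lengths = {r.id: r.length for r in ds.records}
    feat_index = {}
    for f in ds.features:
        feat_index.setdefault(f.genome_id, []).append(f)
    for hit, where in zip(ds.truth, ds.truth_placement):
        kind, ftype = where.split(":")
        seq = next(r.seq for r in ds.records if r.id == hit.genome_id)
        assert seq[hit.left_start:hit.left_start + hit.arm_len] == \
            hit.left_arm_seq
        assert hit.outer_end <= lengths[hit.genome_id]
        # the recorded placement matches an actual feature region
        feats = feat_index[hit.genome_id]
        if kind == "inside":
            assert any(f.ftype == ftype and f.start <= hit.left_start
                       and hit.outer_end <= f.end for f in feats)
        else:
            assert any(f.ftype == ftype and hit.outer_end <= f.start
                       and hit.left_start >= f.start - 100 for f in feats)


def test_gen_dataset_planted_density_ratio():
    """Realized stem_loop:gene planted densities reflect the 10x
    configured multiplier within Poisson sampling noise."""
    ds = gen_dataset(SynthConfig(seed=47))
    bp = {"stem_loop": 0, "gene": 0}
    for f in ds.features:
        if f.ftype in bp:
            bp[f.ftype] += f.length
    planted = {"stem_loop": 0, "gene": 0}
    for where in ds.truth_placement:
        kind, ftype = where.split(":")
        if kind == "inside" and ftype in planted:
            planted[ftype] += 1
    ratio = (planted["stem_loop"] / bp["stem_loop"]) / \
        (planted["gene"] / bp["gene"])
    assert 7 <= ratio <= 13


def test_gen_dataset_outputs_byte_identical(tmp_path):
    for d in ("a", "b"):
        gen_dataset(SynthConfig(n_genomes=2, seed=11), tmp_path / d)
    for name in ("genomes.fasta", "features.tbl", "manifest.tsv",
                 "ground_truth.tsv", "synth_config.yaml"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name


def test_gen_dataset_infeasible_layout_errors():
    with pytest.raises(ValidationError):
        gen_dataset(SynthConfig(n_genomes=1, length_bp=2000, seed=1))
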
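"""Generate a synthetic annotated plastid-like dataset with planted S-IRs.

Writes FASTA + feature table + group manifest + ground truth to
./example_data and prints what was generated. The ground truth lists
every planted inverted repeat, so downstream results can be checked
exactly.
"""
from collections import Counter

from sirscan import SynthConfig, gen_dataset

cfg = SynthConfig(n_genomes=4, seed=7)
ds = gen_dataset(cfg, outdir="example_data")

print(f"genomes   : {len(ds.records)} x {cfg.length_bp} bp "
      f"(GC {cfg.gc_fraction})")
print(f"features  : {len(ds.features)} "
      f"({len(set(f.ftype for f in ds.features))} types)")
print(f"planted   : {len(ds.truth)} inverted repeats")
for where, n in Counter(ds.truth_placement).most_common(4):
    print(f"  {where:<22} {n}")
print("Planted density is 10x higher inside stem_loop features than inside "
      "genes,\nso the enrichment example can recover that ratio.")
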
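"""Per-genome and per-group S-IR length-frequency statistics.

Scans a small synthetic dataset, then prints the dataset-wide
counts-by-length table (head) and a per-group summary: mean S-IR/kbp
and the longest arm reached by at least half of each group's genomes.
"""
from sirscan import SynthConfig, gen_dataset, find_irs, profile_genome, \
    aggregate_group, table1_report
from sirscan.stats import group_summary_table

ds = gen_dataset(SynthConfig(n_genomes=6, n_groups=2, seed=5))
profiles = {r.id: profile_genome(find_irs(r), r) for r in ds.records}

print(table1_report(list(profiles.values())).head(8).to_string(index=False))
print("  -> chance S-IR frequency falls steeply with arm length; the "
      "planted 12-15 bp\n     arms sit on top of that background.")

summaries = []
for group in sorted(set(ds.manifest.values())):
    members = [r for r in ds.records if ds.manifest[r.id] == group]
    _, summary = aggregate_group([profiles[r.id] for r in members],
                                 members, group)
    summaries.append(summary)
print()
print(group_summary_table(summaries).to_string(index=False))
print("  -> 'longest_for_half_bp' is the longest arm present in at least "
      "50% of the\n     group's genomes (17-32 bp in real plastid groups).")
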
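# Methods

## Detection model

A short inverted repeat (S-IR) at left-arm start `i` with arm length
`a` and spacer `s` pairs position `i + k` with position
`i + 2a + s − 1 − k` for `k = 0..a−1`. A pairing is a match when the
two bases are Watson–Crick complements; any pairing involving N is a
mismatch (ambiguous bases never support a pair — non-ACGTN input
residues are collapsed to N on read). Sequences are treated as linear;
no wrap-around across the circular origin is attempted, matching a
naive scan of linearised records.

Defaults: arm 6–60 bp, spacer 0–10 bp, at most one mismatch. Two rules
make reported arm lengths well defined:

* **Terminal-match rule.** Both the innermost and the outermost arm
  pair must be exact matches; the allowed mismatch is internal.
  Without this, every perfect arm-`a` hit would "extend" to `a+1` by
  spending the budget on the new terminal, and per-length counts would
  be meaningless.
* **Maximality and deduplication.** Candidates are generated per
  center (gap position × spacer). For each center the largest
  admissible arm is kept. Among hits sharing an identical outer span,
  only the one with the largest arm survives (ties: fewer mismatches,
  then smaller spacer), so each physical palindrome contributes one
  length to the statistics. Hits with distinct outer spans are all
  kept, even if overlapping or nested around different centers. Each
  physical IR is counted once, not once per strand: the structure is
  strand-symmetric, which the test suite verifies as a mirror-image
  property.

`find_irs` vectorises this over all centers per spacer (pair-match
arrays, cumulative mismatch counts, arg-max arm per center); it scans a
150 kbp genome in a few seconds. `brute_force_irs` enumerates every
(left_start, arm, spacer) triple independently and exists only as an
oracle; the two are compared for set equality on hundreds of random
sequences across GC contents in the acceptance suite.

The output ordering is (left_start, spacer, arm); arm is needed as a
tie-break because two maximal hits around nearby centers can share a
left start and spacer with different spans.

## Frequency statistics

Per-genome profiles count hits by arm length; frequencies are
`1000·count/genome_bp`. Aggregate classes 8+/10+/12+ mean arm length
≥ 8/10/12 (inclusive thresholds, matching how the length classes are
labelled in enrichment reports). Group profiles pool counts and bp.
Two group-level frequencies are emitted because they answer different
questions: the unweighted mean of per-genome S-IR/kbp (each genome one
observation, used in the summary table alongside the min–max range)
and the pooled counts/pooled bp rate (a bp-weighted rate, labelled
separately).

"Longest S-IR for 50% of sequences" is the largest arm length L such
that at least half of the group's genomes contain a hit with arm ≥ L —
the upper median of per-genome maxima, with hit-free genomes
contributing 0. With an even group whose maxima split {18, 24}, the
value is 24: one of two genomes (exactly 50%) reaches 24.

## Feature context and enrichment

Each feature contributes three regions in genome coordinates: before
`[start−flank, start)`, inside `[start, end)`, after
`[end, end+flank)`, with flank 100 bp by default. Regions are not
strand-aware ("before" is always lower coordinates). Flanks are
clipped at genome ends and clipped widths enter the region size. A hit
is counted in every region its outer span overlaps by ≥ 1 bp, so a
boundary-spanning hit contributes to two regions; this multi-count
convention is the only one that needs no tie-break. Overlapping
features of the same type each contribute their own regions, so region
bp can double-count — counting is per feature, not per merged
footprint.

Enrichment divides each (type, region, class) frequency by the
inside-gene frequency of the same class; genes are the most commonly
annotated location and serve as the baseline. A zero or absent
baseline makes the ratio undefined: those classes are logged and
omitted rather than emitted as numbers.

## Similarity grouping

The sequence attributed to a hit is its left arm read 5'→3'; the right
arm is not tallied separately. Abundance ranks count identical arms
over all pooled hits (occurrence events, not genomes). Near-groups
collect arms of the same length within Levenshtein distance ≤ 2 of a
representative — the radius that merges one-substitution families of a
shared repeat. The metric is the standard unit-cost edit distance
(edlib); tests check it against a full dynamic-programming matrix and
for metric axioms. Distance comparisons are restricted to arms of
equal length, though indels remain allowed inside the metric.

## Clustering and PCA

The profile matrix has one row per genome or group and per-kbp
frequency columns: arm lengths 6–30 individually, a pooled ">30" bin,
and the 8+/10+/12+ aggregates. Clustering uses Euclidean distances
with the Ward.D2 criterion — squared distances inside the
Lance–Williams update, heights reported on the distance scale
(scipy's `ward`, which we verified matches R's
`hclust(method="ward.D2")` to full precision; the acceptance suite
re-verifies the heights against a direct Lance–Williams recursion).
Newick export places each merge at depth height/2, so leaf-to-leaf
path lengths equal merge heights.

PCA centers and unit-scales columns by default (sample sd, ddof 1);
whether the original analysis scaled is not knowable, so scaling is a
flag (`pca_scale`). Zero-variance columns — common when long arm
lengths are absent from every genome — are left unscaled with a
warning rather than dividing by zero. Component signs are fixed by
making the largest-magnitude loading positive, so outputs are
deterministic. Retained components number `min(n−1, p)`; their
variances sum to the total variance of the processed matrix.

## Synthetic data: what it emulates, and what it does not

Backgrounds are i.i.d. bases at GC 0.37, emulating AT-rich plastid
composition. Such backgrounds already contain ~35–45 chance S-IRs/kbp
(dominated by arms 6–8), which is the realistic null against which
planted signal must be read. Defaults are 8 genomes × 24 kbp — desk
scale relative to real plastid genomes (11 kbp–1 Mbp, typically
120–150 kbp) — with a feature layout (gene, CDS, tRNA, rRNA, exon,
intron, stem_loop, repeat_region, regulatory, misc_feature) sized so
16 gene and 8 stem_loop features per genome fit with realistic gaps;
the gene count gives the enrichment baseline ≈130 expected planted
repeats, keeping the estimated ratio's sampling error under 10%.

Planted IRs are placed by a Poisson process per region at
`base_density × multiplier` (defaults: gene baseline 2/kbp inside
features; stem_loop 10×, intron 2.4×, regulatory 3.2×, rRNA 0.2×, and
7.6× in the 100 bp window before repeat_region — the qualitative
enrichment pattern of real plastid annotations). Planted arms are
12–15 bp so recovery is measured on the 12+ class, where the chance
background (~0.05/kbp) is negligible next to the planted 2/kbp
baseline; on the "all" class the chance background would swamp any
plantable signal, which mirrors the real-data situation where
enrichment is strongest in the longer classes. Placement samples
uniformly over exactly-computed free positions; if a region fills, the
remaining draws are dropped and the ground truth records only what was
planted.

Two constructions make planted arm lengths unambiguous. Spacer bases
are drawn from {A, C}, an alphabet in which no Watson–Crick pair can
form, so no wider-armed candidate sharing the planted outer span
exists. For exact-recovery tests the whole locus window (span + 2 bp
margins) is *screened*: rewritten with {A, C} residues, provably
IR-free (and still verified so with the brute-force oracle), which
also blocks extension past the planted terminals. Screened loci are
deliberately artificial — they exist to make recovery deterministic,
and passing them shows the detector's correctness, not its behaviour
amid overlapping chance repeats; that behaviour is covered by the
oracle-equivalence suite on unscreened random sequence.

What the generator does not model: phylogenetic structure or sequence
evolution (group labels are arbitrary partitions), codon structure or
real annotation nesting (gene/CDS/exon are laid out independently),
the quadripartite LSC/IRa/SSC/IRb architecture (a `repeat_region`
feature stands in), and circularity. Passing tests therefore
demonstrate algorithmic correctness and statistical recovery under a
controlled null, not biological realism of any particular frequency
value.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; NCBI feature tables
  and GFF3 (both 1-based inclusive) are converted at the boundary, and
  feature tables written by the package use swapped coordinates for
  the minus strand.
* Report floats are written with `%.6g` and no timestamps, so reruns
  on identical inputs are byte-identical; report headers echo only the
  parameters their stage consumes, so e.g. changing the flank leaves
  scan outputs untouched.
* Degenerate inputs: empty sequences yield empty hit lists; empty
  FASTA files, zero-length records, duplicate manifest entries and
  intervals beyond the genome end raise typed errors (CLI exit code 1;
  unexpected failures exit 2).
* Desk-scale problem sizes throughout the tests (hundreds of 0.5–2 kbp
  sequences for oracle equivalence, 8 × 24 kbp for enrichment
  recovery) were chosen so the full suite runs in well under a minute
  of scan time while keeping Poisson sampling error inside the stated
  recovery bands.

## Known limitations

* The maximality/deduplication convention is one reasonable fixed
  choice; other IR finders resolve nested and same-span candidates
  differently, so absolute counts are comparable only within this
  package.
* Levenshtein grouping is seeded by exact-abundance ranking; it is not
  a clustering of the full arm pool, and a family whose members are
  all rare can be missed.
* Enrichment ratios inherit annotation quality: overlapping same-type
  features double-count, and no attempt is made to deduplicate
  redundant annotations.
* The scanner is O(max_arm × max_spacer × n) with numpy constants;
  genomes beyond a few Mbp are feasible but the per-genome hit lists
  (tens of thousands of hits per 100 kbp) dominate memory in the
  similarity stage.
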
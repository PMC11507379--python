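# Methods

This note records what `numtkit` computes, the assumptions behind it, the
parameters that matter, and the choices made where the design was open.

## The annotation model

A Numt is modelled as one historical insertion event: a contiguous segment
of the circular mitochondrial genome copied into nuclear sequence, possibly
diverged since insertion and possibly split later by other insertions
(transposons). The pipeline therefore has two levels:

* **HSP** — one local alignment between nuclear sequence and the
  mitochondrial reference. Length statistics are tabulated over the number
  of aligned mitochondrial bp per HSP.
* **Merged locus** — the transitive closure of HSPs lying within
  `max_gap_nuclear` = 2000 bp *and* within `max_gap_mito` = 2000 bp
  (circular distance) with consistent orientation. This is the unit counted
  as "one Numt".

"Within 2000 bp" is read as the **nearest-end gap** (overlap counts as
gap 0), not start-to-start distance, so fragments flanking an inserted
repeat merge back into one locus. "Consistent orientation" is implemented
as: same strand, and walking along the nucleus must advance along the
circle in the direction the strand implies. Both conditions are combined by
measuring the *directed* circular gap from the nuclear-earlier HSP's
mitochondrial end to the nuclear-later HSP's start (reversed on the minus
strand) and requiring it ≤ 2000 bp; overlapping mitochondrial intervals
always qualify. The circular-gap convention is not uniquely determined by
the problem; this directed form was chosen because it encodes the ordering
constraint and the distance bound in one test, and it is configurable via
`MergeParams`.

### Circularity

Discovery runs with the plain reference; merged loci are then **refined**
by re-searching their extracted sequence with the reference concatenated
twice (`double_reference`). On the doubled sequence an origin-spanning
insertion is one contiguous alignment; `wrap_interval` maps doubled
coordinates back to the circle, yielding either a single segment `[s, e)`
or the two-segment comma-pair form `[s, L),[0, e′)`. Mirror artifacts of
the doubling (the same hit shifted by +L, and partial hits of an
origin-spanning alignment's two halves) are removed by shifting
second-copy hits by −L and discarding any hit whose nuclear and circular
footprint lies inside a higher-scoring one. Loci that fail refinement are
flagged `unconfirmed` and excluded from summaries (but retained in the
locus table) — only confirmed final HSPs are tabulated.

## Alignment backends

`AlignmentParams` fixes the scoring scheme (+2 match, −3 mismatch, −5 gap
open, −2 gap extend; a length-k gap costs 5 + 2k) and the e-value cutoff
10⁻³.

* **external_blastn** (default): NCBI `blastn -task blastn` in pairwise
  subject/query mode with exactly those scores. This is the production
  backend. Low-complexity filtering is disabled because the package's test
  substrate is unmasked synthetic sequence; real-genome runs can re-enable
  masking upstream.
* **builtin**: exact k-mer seeding (word size from `word_size`), seed
  chaining on near-constant diagonals, and banded affine-gap local
  alignment (exact Gotoh DP within the band, numba-compiled) around each
  seed cluster. E-values use the Karlin–Altschul form *E = K·m·n·e^(−λS)*
  with λ solved for the +2/−3 scheme at uniform base composition
  (λ ≈ 0.634) and K fixed at 0.21. These e-values are approximate: the
  builtin exists so the full pipeline runs with no external binaries, and
  agreement with an exhaustive Smith–Waterman oracle is asserted on
  identity, not on e-values. Parity with published scans is defined by the
  external engine.

`word_size` defaults to 7 for both backends. The engine's own default (11)
requires an exact 11-mer shared with the reference; for a 100 bp insertion
diverged 15% the chance of no clean 11-mer is a few percent, so short old
Numts would be missed. Word size 7 makes recovery of ≥ 100 bp segments at
≤ 15% divergence essentially certain while the e-value cutoff keeps random
hits out.

## Dimorphism calling

Inter-assembly insertion/deletion variants are **ingested**, never
recomputed: whole-assembly alignment and variant calling (e.g. minimap2 +
paftools at asm20 settings) is a backend contract, and the synthetic
generator emits exactly the deletions such a caller would report. The
bespoke content is the intersection logic:

* a deletion covering ≥ 0.90 of an HSP (fraction of the *HSP*, asymmetric)
  marks it absent; `absent_large_sv` when the variant exceeds the HSP
  length by **more than** 1000 bp (strictly), else `absent_clean`;
* among multiple qualifying variants the one with maximal overlap fraction
  wins, ties broken by smallest length difference (the choice only affects
  the clean/large label; all qualifying variants are kept as support);
* insertions relative to the reference are scanned against the doubled
  mitochondrial sequence; coverage ≥ 0.90 of the insertion →
  `inserted_clean`, an embedded hit in an insertion > 1000 bp longer than
  the aligned span → `inserted_large_sv`; no hit → no call. Insertions in
  the intermediate zone (coverage below 0.90 but length within the margin)
  are labelled clean, as Numt-dominated events.

Welch's unequal-variances *t*-test (with Welch–Satterthwaite degrees of
freedom) compares per-HSP identity between classes; identical groups are
reported as t = 0, p = 1. Significance labels follow the conventional
ladder (`****` < 10⁻⁴ … `ns`).

## Population scanning

Deletion SVs match loci by **90% reciprocal overlap** (both directions).
Insertion queries are the full ALT sequence, or left + 10 Ns + right for
partially assembled insertions. Internally the scanner splits each query at
runs of ≥ 10 Ns and searches the pieces separately, mapping coordinates
back — this guarantees by construction that no reported HSP spans the
N-join. Classification imposes no coverage floor: any retained HSP makes
the insertion a Numt (the 0.90/1000 bp rules belong to the assembly
comparison, not here). A sample carries a Numt when its alt-allele count is
≥ 1 (configurable in principle to dosage sums; genotype dosage is not used
because presence/absence is the biological question); missing genotypes
never count. Category summaries report n, median (midpoint convention) and
min–max range.

## Outgroup presence

Loci are extracted with 10 kbp flanks (clipped and flagged at contig
edges). Alignments of the extract to the outgroup are chained into
candidate hits and filtered: ≥ 2000 **aligned bases** within each flank
region (aligned-base count, not span — a sensitive aligner reports blocks,
and anchored bases are what orthology needs) and ≥ 80% aligned coverage of
the Numt interval, all thresholds inclusive. The best candidate (total
aligned bases) is re-queried against the mitochondrial reference:

* confirmation hit → **present**;
* flanks anchored (≥ 2000 bp each) but the Numt interval uncovered or
  unconfirmable → **absent** — the orthologous position exists without the
  insertion;
* no alignment anchoring both flanks → **unresolved**.

## Synthetic fixtures

`synth_fixtures` generates every input with ground truth, all
bit-reproducible under a seed. It emulates: a uniform-random circular
mitochondrial genome (default 16,727 bp, the scale of the canine
reference); nuclear scaffolds (default 5 × 200 kb chromosomes + 1 × 50 kb
unplaced contig) with planted Numts; assembly pairs with clean or
flank-removing excisions plus the deletion records an assembly-alignment
caller would emit; and a genotyped SV VCF with full or edge-only insertion
sequences plus random-sequence decoys.

Default plant conditions: 50 Numts, lengths 100–5000 bp, substitution
divergence uniform on 0–15% with small indels at 0.002/site (geometric
lengths, mean 3 bp), half on the minus strand, 20% origin-spanning, 10%
fragmented by a 500 bp random disruptor. Plants are separated by ≥ 3 kb so
distinct insertions can never co-merge under the 2000 bp rule — boundary
recovery is then attributable to alignment behaviour alone. The divergence
model is substitutions + short indels only (no rearrangement, no repeat
landscape, uniform base composition); passing tests therefore demonstrate
the interval logic and circularity handling, not robustness to real repeat
content or compositional bias, which only the external backend on real
data exercises.

Preset problem sizes (basic 50 Numts in 1.05 Mb, dimorph 50/15 excised,
population 100 samples × 30 variants, outgroup 12 loci in 0.8 Mb) keep a
full end-to-end run in tens of seconds while leaving every code path —
origin wrap, fragmentation, partial insertions, missing genotypes,
excisions — represented several times over.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; reports print 1-based
  inclusive. BED names render circle intervals 0-based (`16000-16727,0-273`).
* Alignments longer than one full circle turn (possible for tandem or
  gap-inflated hits) are clipped to one turn before wrapping.
* `unify_numt_lists` collapses loci whose starts *and* ends each differ by
  ≤ 10 bp, by transitive closure; the unified span is the union, and the
  result is independent of source order.
* Median over an even count uses the midpoint, hence half-integral values.
* Empty inputs return empty outputs everywhere except file readers, which
  treat an empty FASTA/VCF as a format error.

## Known limitations

* Builtin-backend e-values are approximate (ungapped λ, fixed K); borderline
  hits near the cutoff may differ from the external engine.
* The builtin seeder bounds diagonal drift (±20 per step, ±100 per
  cluster), so alignments with > ~100 bp net indel imbalance split into
  chained HSPs rather than one.
* Whole-genome alignment, read-level genotyping and repeat annotation are
  out of scope; their outputs are consumed, not produced.
* The gene-context classifier is interval-based (exon > intron >
  intergenic, CpG flag on ≥ 1 bp overlap); it does not interpret gene
  models beyond intervals.
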
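# Methods

This note documents the models, definitions and defaults behind each
component, the design choices made where conventions genuinely diverge, and
what the synthetic fixtures do and do not establish about real data.

## Barcode space and whitelist

A split-pool design with plates of sizes *n₁…n_k* (sub-barcode lengths
*l₁…l_k*) yields the whitelist as the Cartesian product of the plates:
∏ᵢ nᵢ full barcodes of length Σᵢ lᵢ, enumerated round-major and
well-ascending so serialization is byte-deterministic. Defaults follow the
canonical design: three rounds of 96 ten-mers → 884,736 thirty-bp barcodes.
Because every plate has uniform sub-barcode length, concatenation
boundaries are fixed and the product is automatically a bijection onto well
tuples; the collision check in `build_whitelist` is defensive for any
future variable-length extension. `min_pairwise_hamming` exists because
unambiguous 1-mismatch correction requires within-plate distance ≥ 3; the
CLI warns below that.

## Parsing and tiered correction

Parsing is strictly fixed-offset. Each linker is verified within a
per-linker mismatch budget (default 1); a read failing any linker is
counted as a parse failure and never corrected — a 1-bp frameshift shifts
every downstream linker out of register, so this check is what rejects
frameshifted reads. No indel rescue is attempted.

Correction finds the minimal tier *t* ≤ `max_mismatch` (default 1,
configurable to 3) with at least one whitelist entry at Hamming distance
exactly *t*, and assigns only a unique candidate; ties are rejected rather
than broken, because an arbitrary tie-break would risk merging material
from different cells. Implementation: tier 0 is a hash lookup; tier 1
enumerates the 3·L substitution neighborhood against the hash set; tiers
2–3 use a pigeonhole block index (an entry within distance *d* of the query
must match it exactly in at least one of *d*+1 blocks), followed by exact
distance evaluation of the few candidates. Both routes are exactly
equivalent to an exhaustive nearest-neighbor scan, which the test suite
verifies on 10⁴ queries against a 10⁴-entry whitelist.

The report partitions reads exactly: total = parse failures + Σ per-tier
assignments + ambiguous + unassigned. UMIs are passed through verbatim; no
quality-aware or UMI-network correction is performed at this stage.

## ATAC metrics

Coordinates are 0-based half-open everywhere. A *unique fragment* is a
distinct (chrom, start, end) per barcode; the count column is PCR duplicate
multiplicity. The Tn5 +4/−5 offset is assumed already applied by the
upstream fragment generator and is not re-applied.

- **Duplication rate** = 1 − unique fragments / total read pairs. Undefined
  (absent, not 0) for barcodes with no fragments.
- **TSS enrichment**: both ends of each unique fragment are insertion
  sites, binned at 1 bp in a strand-oriented ±2000 bp window around each
  TSS. The per-barcode score is the 51-bp moving-average depth at the TSS
  divided by the mean raw depth over the two outermost 100-bp flanks; zero
  flank coverage gives a missing score, never infinity. There is no single
  community-standard definition of this score — window, flank and smoothing
  widths are config keys, and absolute values are comparable only under a
  fixed definition.
- **FRIP**: unique fragments overlapping ≥ 1 bp of the internally merged
  peak set, over unique fragments, with half-open semantics (a fragment
  ending where a peak starts does not overlap).
- **Cell calling** applies inclusive thresholds (`unique_fragments ≥
  min_fragments`, `tss_enrichment ≥ min_tss`; defaults 1000 and 5, with 7
  the stricter preset for mixed-species runs). Thresholds are always
  explicit parameters; knee-style auto-thresholding is deliberately out of
  scope. NaN scores never pass.

## Barnyard classification

Strictly pairwise. Purity is the majority-species fraction of a barcode's
counts (unique fragments for ATAC, UMIs for RNA — the classifier is
agnostic). A barcode below `min_total` (default 1000, tied to the ATAC
cell filter) is `low_signal`; otherwise it is called for the majority
species when purity ≥ threshold (non-strict ≥, default 0.95 — the
inclusive reading of a "minimum purity"), else `doublet`. The summary's
doublet rate is doublets / (pure + doublets), excluding low-signal
barcodes.

## RNA counting and filters

Counting is defined on a post-alignment read-to-gene assignment table
(barcode, UMI, gene, mapped flag), keeping the contract independent of any
aligner's barcode-geometry options. count(b, g) = number of distinct UMIs
among mapped records; collapse is exact-match — no 1-mismatch UMI network —
which is simpler and deterministic, at the cost of slightly inflating
counts under sequencing errors relative to network-collapsing aligners.
Mapped records with empty UMIs are dropped and tallied.

Filters run cells-first, then genes: keep cells with detected genes ≤ 4000
and mitochondrial UMI fraction ≤ 0.01 (both inclusive — a 4001-gene cell is
removed), then keep genes expressed in ≥ 3 remaining cells. Mitochondrial
genes come from an explicit set and/or name prefix; nothing is hard-coded.
Sequencing efficiency = total matrix UMIs / total sequenced reads.

## Bead image QC

Foreground/background by Otsu's threshold (between-class variance maximum
on the grayscale histogram; foreground strictly above the threshold, which
the tests pin against an exhaustive 256-bin search). Beads are circles
found by a circle-Hough transform on the foreground boundary, with
non-maximum suppression keeping centers at least one minimum radius apart
and a minimum-radius gate (default 5 px) that rejects ~1 µm punctate
debris. A bead's score is the mean intensity over a 2 px-radius center
disc (damping shot noise versus the single center pixel) minus the mean
background intensity; center scoring is preferred over whole-bead
integration because focus differences mostly perturb intensity near the
bead edge. Scores are therefore invariant to global additive offsets.

The positive/negative cut is not a property of the assay and must be
chosen: the default is 3 background standard deviations above zero on the
background-subtracted scale, always overridable and recorded in the
summary. The positive fraction uses the brightfield detection count (or a
manual count) as denominator, with a Clopper–Pearson exact binomial CI.
Exposure normalization across probe panels is out of scope; cross-image
comparability is the user's responsibility.

## Synthetic data: what it emulates, and what it does not

Each generator is a single seeded PRNG stream and emits a truth table;
identical (seed, config) gives byte-identical output.

- **Barcode reads**: substitutions are injected i.i.d. per base *within the
  sub-barcode blocks only*, so assignment tiers follow a
  Binomial(30, ε) law exactly and the suite can test against the closed
  form; linkers are emitted clean. Frameshifts delete one random base and
  pad the read end, emulating oligo-synthesis deletions. Defaults (ε =
  0.01, 9% frameshift fraction) reproduce the error regime of real
  libraries, giving ≈ 88% of reads assigned at one allowed mismatch.
- **Fragments**: cells place a fraction λ = 0.45 of insertions at
  Normal(TSS, 75 bp) and the rest uniformly over a two-chromosome, 1 Mb toy
  genome with 200 TSSs and ±250 bp peaks; insert lengths are uniform
  80–140 bp; duplicate multiplicities are Geometric(1/4), i.e. a ~75%
  expected duplication rate (E[dup] ≈ 1 − 1/mean). These defaults land
  cells at TSS enrichment ≈ 10–20 and FRIP ≈ 0.5, the regime of a
  good-quality nuclei library, with 2000 unique fragments per cell over a
  diffuse ~30-fragment background population.
- **Barnyard**: pure cells leak 0.5% of counts to the other genome;
  doublets split at a Beta(20, 20) ratio, so their purity stays far below
  0.95 and planted doublet fractions are recovered to binomial error.
- **RNA assignments**: per-gene molecule counts are Poisson with 0.5% of
  expression routed to a mitochondrial gene; molecules are duplicated
  Geometric(1/2.5) and padded with unmapped reads to a 55% mapped fraction,
  so efficiency ≈ 0.55/2.5 = 22%.
- **Bead images**: non-overlapping discs (radius 9 px) on a jittered grid,
  positives at a high plateau, Gaussian noise σ = 3 on 8-bit images.

What passing on these fixtures does **not** show: real barcode reads have
position-dependent and quality-correlated errors, real linkers also
acquire errors (the generator keeps them clean to preserve the analytic
oracle), real fragment libraries have nucleosomal insert-size structure
and chromosome-scale coverage biases, real ambient RNA/chromatin
contaminates background barcodes, and real images have illumination
gradients and focus drift. Headline numbers from deposited sequencing runs
(tier percentages, per-cell medians, species-purity rates) additionally
depend on genome alignment and peak-calling choices that sit outside this
toolkit, so the suite validates definitions, invariants and ground-truth
recovery rather than reproducing those published values.

## Numerical and degenerate-input conventions

- Hamming comparison requires equal lengths; mismatched lengths are errors,
  never truncated.
- Empty inputs: duplication/FRIP/TSS for an absent barcode are absent, not
  zero; an empty TSS set, a constant image, an empty background mask and a
  zero read count are hard errors.
- Ambiguity in correction is recorded (tier and candidate count) rather
  than resolved.
- All sparse matrices are integer CSR; MTX round-trips exactly.
- Problem sizes in the test and acceptance runs (e.g. 2 × 10⁴ reads for
  tier statistics, 300 + 3000 barcodes for cell calling, five to ten
  960-bead images) are chosen so every stochastic check has ≥ 3σ headroom
  while the whole suite stays fast on a laptop.

## Known limitations

- No indel-tolerant barcode recovery: frameshifted reads are counted, not
  rescued (by design, matching the fixed-offset chemistry readout).
- No quality-score-aware correction; no UMI error network.
- The TSS score is definition-dependent; compare absolute values only
  within one configuration.
- The bead positive threshold default (background + 3σ) is a heuristic and
  should be reviewed against controls for dim probes.
- `classify_table` / `classify_species` handle exactly two species.
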
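# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Study design assumptions

The pipeline targets a two-condition small-RNA/degradome design with **one
sequencing library per condition** and a transcript (unigene) set instead
of a genome. Single libraries mean no biological replication: the only
identifiable noise is counting noise, which is why differential expression
uses an exact conditional test rather than a dispersion-based count model,
and why the simulator draws Poisson counts by default (a negative-binomial
option exists for sensitivity checks, but its dispersion is not
identifiable from such a design).

## Read cleaning (preprocess)

Rules run per read in a fixed order, first failure claims the read, so the
rejection tally plus the retained count always partitions the input:
mean Phred < 20 (skipped for FASTA input) → 3′ adapter trimming
(exact match, minimum overlap 6 nt, ≤ 1 mismatch, leftmost occurrence) →
adapter-only / 5′-adapter contamination → any ambiguous base → poly(A)
(≥ 80% A) → length outside [18, 30] nt. All thresholds are configuration;
the source protocols never state them precisely, so they are conventional
Illumina-era defaults, not fidelity claims. The library's `clean_total` is
recorded independently of the unique-tag map because it is the
normalisation denominator — tags later annotated away still count.

## Annotation cascade

Classes are assigned with fixed precedence: structural ncRNA (rRNA > tRNA >
snRNA > snoRNA > other ncRNA, by exact substring on either strand) before
conserved miRNA, before unannotated. Conserved matching is ungapped and
end-to-end against a mature reference, U/T-equivalent, allowing ≤ 2
substitutions; references longer by up to 2 nt are slid over the tag (no
indels — the matching allowance is stated in mismatches only). Ties break
to the lexicographically smallest reference id, making results
order-independent. Transcript mapping is annotational (exact, both
strands, 1-based forward-strand coordinates) and does not change a class.
Family names are parsed from identifiers (`...miR166a-3p` → MIR166);
unparseable ids go to family UNKNOWN with a warning.

## Hairpin discovery

Folding is a pluggable contract. Default engine: ViennaRNA's MFE fold via
its python bindings. Fallback: a deterministic energy-weighted
base-pair-maximisation dynamic programme (GC −3, AU −2, GU −1 kcal/mol,
minimum loop 3, ties broken toward the unpaired/leftmost traceback). The
fallback has no stacking or loop entropy terms; it is adequate for the
idealised stems the simulator plants and keeps the package self-contained,
but its energies are not thermodynamic — hence "lower fidelity".

Around each transcript hit of an unannotated tag, two windows are excised
(tag at the 5′ end plus 150 nt downstream; tag at the 3′ end plus 150 nt
upstream), clipped and deduplicated. Each window is folded, then **trimmed
to the stem-loop around the tag** (the span of the mature and all its
pairing partners, padded 15 nt per side) and refolded: the flank of an
excision window folds independently of the hairpin, and judging criteria
on the untrimmed window would reject real precursors for accidental
micro-hairpins in the flank. For the same reason the single-terminal-loop
criterion is evaluated within the mature's stem-loop span, not over the
whole precursor string.

Acceptance flags (all configurable): mature length 20–23 nt; precursor
60–300 nt; mature wholly within one arm (no partner inside the mature, all
partners one side); duplex mismatches ≤ 4 (leading/trailing unpaired
mature bases beyond the 2-nt overhang, plus symmetric interior loop
positions); bulged nucleotides ≤ 2 (interior loop asymmetry); MFE ≤ −18
kcal/mol; one terminal loop. A candidate passes iff all flags hold. When
both windows pass, the higher |MFE|/nt window wins; overlapping precursors
on a transcript deduplicate to the higher-count mature (either strand —
the mature's reverse complement sits in the opposite arm and would
otherwise duplicate every locus). The star strand is located by the 2-nt
3′ overhang rule (its 3′ end two past the partner of the mature's 5′-most
paired base) and reported with its per-library counts; zero counts are
evidence-tier information, not grounds for rejection. Candidates need a
default minimum of 3 supporting reads across libraries.

## Differential expression

RPM = count/N × 10⁶ at full float precision; rounding (half away from
zero) happens only at reporting time. log₂ fold-change floors a zero RPM
at 0.01 — the floor is recoverable uniquely from the zero-count rows of the
published tables this package audits (244 → 0 gives −11.16 only with 0.01).

The tag-count test works on the conditional law p(y|x) above. Tails are
computed in log space with `gammaln`; the decaying side is summed directly
(downward to 0, or upward in chunks until a geometric-series bound on the
remainder is below 10⁻¹⁵ of the partial sum), the other side by exact
complement. The default two-sided convention is the **CDF split**
p = min(1, 2·min(P(Y≤y), P(Y>y))). Three properties motivated it:

- it reproduces published two-library p-values row by row (e.g. 0 vs 10
  reads at ~10.7 M totals gives 9.87×10⁻⁴; 10 vs 28 gives 3.45×10⁻³),
  where the textbook "include the point mass in both tails" doubling is
  off by up to a factor 2;
- it is exactly swap-symmetric: the conditional pmf satisfies
  p(y|x; N₁,N₂) = p(x|y; N₂,N₁) pointwise, which makes the swapped lower
  tail equal one minus the unswapped lower tail (an incomplete-beta
  identity), so p(x,y,N₁,N₂) = p(y,x,N₂,N₁) to machine precision;
- for x = y with N₁ = N₂ the lower tail is exactly ½ (I₀.₅(n,n) = ½), so
  the p-value is exactly 1.

The more conservative inclusive doubling is available as
`convention="inclusive"`; the two differ by at most the point mass at the
observed count. A numeric guard returns exactly 1.0 whenever the smaller
half is ≥ ½ − 10⁻¹². Thresholds are inclusive (|fc| ≥ 1.0, p ≤ 0.05). No
multiple-testing correction is applied by default, matching the design
being reproduced; Benjamini–Hochberg is available behind a flag.

## Degradome target calling

Tags map perfect-match, sense strand, each contributing its count at its
5′-most base; multi-mapping tags count at every locus and are flagged
rather than fractionally split (determinism and transparency). Site
scoring: Watson–Crick 0, G:U 0.5, mismatch 1, each gapped position 2; the
alignment is rejected above 4 points or when the bases opposite miRNA
positions 10–11 are not strict Watson–Crick pairs — a G:U wobble does not
count as a pair at the cleavage site. The slice position is the transcript
base paired to miRNA position 10 (s + L − 10 for an ungapped site
[s, s+L−1]; a pairing walk resolves gapped alignments). The production
scanner is ungapped and vectorised; it is property-tested against a
brute-force all-windows scorer.

Events require ≥ 1 degradome read at the slice position (configurable).
Categories use the transcript's signature profile with the median taken
over positions carrying ≥ 1 read only (zero positions excluded, matching
t-plot practice): abundance equal to the maximum → I; above the median but
below the maximum → II; at or below the median → III. Category labels are
invariant under uniform scaling of a transcript's abundances. Sites
overlapping miRNA-generating loci can be excluded (`exclude_regions`) —
a hairpin's star arm is trivially near-complementary to its own miRNA and
would otherwise always surface as a "target" as soon as background
degradome signal covers it; the pipeline passes the discovered precursor
spans. One event per (miRNA, transcript, slice position); alternative
alignments resolve by lowest score then leftmost site.

## Synthetic data generator

Every generator is a pure function of (parameters, seed); each mixes a
distinct domain constant into its RNG stream so that reusing one seed
across stages does not correlate their draws.

- **Transcriptome**: i.i.d. bases at a configurable GC content; default 40
  transcripts × 800 nt.
- **Hairpins**: perfect stems (14 bp pad + 21 nt mature arm + 10 nt loop +
  reverse complement, mature on a random arm), optionally perturbed on the
  star side (substitutions → 1×1 interior loops; insertions → bulges),
  folded and re-checked against the acceptance criteria before insertion.
  Requests outside the criteria limits are refused.
- **Libraries**: per-miRNA condition-1 RPM levels and true log₂
  fold-changes, Poisson counts with mean RPM × depth/10⁶, star tags at 10%
  of the mature level, plus background tags rejection-sampled to stay > 2
  mismatches from every planted mature so truth labels are unambiguous.
  Default levels are deliberately bimodal — a low tier (3–40 RPM, like
  novel miRNA candidates) and a high tier (1 000–50 000 RPM, like dominant
  conserved families) — mirroring the dynamic range such libraries show,
  with the large fold-changes cycled on the high tier, where a
  single-library Poisson design can actually resolve them.
- **Degradome**: one tag of count `peak_height` starting exactly at each
  planted slice position, plus Poisson(background_rate × peak_height)
  reads at every other transcript position.
- **Raw reads**: clean tags wrapped with the 3′ adapter and padded to 50
  nt, plus counted contaminant classes (adapter-only, short inserts,
  poly(A), low quality, N-containing, oversized inserts) for exercising
  the cleaning cascade.

What the generator does **not** emulate: position-specific sequencing
error, quality-score profiles beyond a mean, ligation bias, isomiR
heterogeneity, overdispersion between biological replicates, and RNA
secondary-structure effects on degradome coverage. Passing tests therefore
demonstrate correctness of the algorithms under idealised counting noise,
not performance on real libraries.

## Default problem sizes

The shipped end-to-end configuration plants 20 hairpins and 20 cleavage
sites in a 40 × 800 nt transcriptome at 10⁶ clean reads per condition,
degradome peaks of 50 reads over a 10% background — large enough that
recovery metrics are meaningful, small enough that the full pipeline runs
in seconds on one CPU.

## Known limitations and recorded discrepancies

- The published table this package audits contains one internally
  inconsistent row: counts 2 251 vs 3 231 give a fold-change of 0.5185
  (prints as 0.52) but the table prints 0.51, and the row's p-value is
  ordered inconsistently against its sibling row. 75 of 76 printed
  fold-changes reproduce exactly; this one is reported as a mismatch
  rather than special-cased.
- Three printed p-values (1.45×10⁻¹, 4.57×10⁻¹, 5.48×10⁻²) exceed the
  stated 0.05 cut-off although their rows are included in the published
  down-regulated tally; the reproduction report flags exactly these rows,
  and the published count of 15 down-regulated is consequently not
  reproducible under the stated rule.
- Published family shares are truncated, not rounded (86.3563% prints as
  86.35%); comparisons allow one unit in the last printed digit.
- The fallback folding engine's energies are heuristic; MFE-dependent
  statistics (e.g. mean precursor MFE) are only comparable across runs
  using the same engine.
- Dataset-level results of the original study (its 45 conserved miRNAs, 31
  novel candidates, 53 targets and category split) require the original
  sequencing libraries and are out of scope; the pipeline's correctness on
  those stages is established against the synthetic truth table instead.
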
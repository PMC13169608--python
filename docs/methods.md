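# Methods

## Counting model

The unit of analysis is one configured two-exon splicing event: exon 1,
intron 1 and exon 2, contiguous in 1-based inclusive genomic coordinates,
normalized internally to 0-based half-open intervals. The donor site is the
first intronic base, the acceptor site one past the last, so a canonical
spliced alignment carries an `N` skip exactly equal to the intron interval.

Every mapped record whose reference span (including `N` skips) overlaps the
analysis region — the exon1..exon2 span padded by the junction window — is
assigned exactly one category by the first matching rule:

1. **canonical_junction**: some `N` skip matches the intron. Default
   matching is *windowed*: both skip edges within `window_bp` (default 50)
   of the donor and acceptor respectively; *exact* mode requires equality.
   At least `min_overhang_bp` (default 1) aligned bases are required on each
   side of the matching skip.
2. **cryptic_junction**: some `N` skip starts within `window_bp` of the
   donor but ends strictly inside the intron, beyond the acceptor window —
   the exon1→pseudo-exon split-read signature. Same overhang requirement.
3. **intron_contained**: no `N` operation at all, and every aligned block
   (maximal M/=/X runs, deletions merged) lies fully within the intron.
4. **unclassified**: everything else.

Junction rules precede containment, so a spliced read can never count as
intron-contained; the two informative definitions are disjoint. Windowed
matching is the default because splice-site-adjacent alignment jitter is
common in practice; exact mode is available for strict reproduction. The
1-bp overhang is the weakest rule consistent with "spanning" a junction —
any stricter value is a flag away.

Cryptic-junction reads are reported as their own category and excluded from
both PSI terms: the PSI and efficiency formulas are defined over junction
and intron counts only, and folding cryptic reads into either term would
change the estimand silently. They surface instead in the per-sample
junction table, where each distinct (donor, acceptor) skip is aggregated
with its supporting read count and labelled canonical / cryptic / other by
the same window rules.

### Filters and counting modes

Defaults are permissive — MAPQ threshold 0, duplicates kept, secondary and
supplementary alignments dropped — because the category rules themselves
define the analysis. `per_record` mode (default) classifies and counts each
mate independently, matching a per-record SAMtools-style extraction.
`per_fragment` mode counts each query name once, collapsing mate labels by
*informative consensus*: an unclassified mate never vetoes an informative
one; two distinct informative labels resolve to unclassified. This is a
deliberate refinement of "mate disagreement is unclassified" — a junction
mate paired with an exonic mate is unambiguous evidence, and discarding it
would bias fragment counts downward for no gain.

## Metrics

With junction count *j* and intron count *i*: PSI = *i*/(*j*+*i*),
efficiency = *j*/(*j*+*i*). Both are undefined when *j*+*i* = 0 and are
propagated as not-available (TSV `NA`), never coerced to 0, so a silenced
locus cannot masquerade as perfect splicing. The PSI confidence interval is
Clopper–Pearson (exact binomial, default 95%, via the beta quantile).
Replicate summaries report mean and sample SD (n−1) over defined replicate
values, with the number of excluded undefined replicates.

## Group comparison

Pairwise tests use counts pooled across replicates within each group — a
single exact test per pair is only defined on pooled counts — with the
per-replicate mean ± SD reported alongside. The test is the two-sided
Fisher exact test under the point-probability rule: p is the total
hypergeometric probability of all tables, with the observed margins, whose
point mass does not exceed the observed table's. Two-sided Fisher variants
differ, so the rule is stated explicitly.

For grand totals up to 1024 the p-value is computed with exact integer
arithmetic: point masses share the denominator C(n, c₁), numerators
C(r₁, a)·C(n−r₁, c₁−a) are exact integers, tie decisions are integer
comparisons, and the single final division is correctly rounded. Above that
total, point masses are evaluated in floating point (vectorized
hypergeometric log-pmf) and ties resolved with the 1e-7 relative tolerance
conventional in exact-test implementations; at those sample sizes exact
rational arithmetic would multiply thousands of multi-thousand-digit
integers for no measurable difference in p. A p-value that underflows the
double range is reported as the smallest positive subnormal (5e-324) rather
than 0, since the observed table always has positive mass.

The reported odds ratio is the sample cross-product ratio (a·d)/(b·c)
(infinite when b·c = 0 with a·d > 0, not-available for 0/0), not the
conditional maximum-likelihood estimate some libraries return. No
multiple-testing adjustment is applied by default; Bonferroni and
Benjamini–Hochberg are available and operate over the full testable pair
set. Pairs involving a group with zero informative reads are flagged
not-testable and do not affect the others.

## Coverage tracks

Depth at a base is the number of filtered records with an *aligned* base
(M/=/X) there; `N`-skipped, deleted and clipped bases contribute nothing.
Counting deletions as coverage would be defensible but is not what "read
coverage depth" conventionally means; the choice is fixed here so outputs
are exactly reproducible. Pair scaling divides both tracks of a
user-declared pair by the single pair-wide maximum raw depth, mapping the
deeper track's peak to 1.0; an all-zero pair is returned unscaled and
flagged rather than divided by zero. Output is run-length-merged bedGraph
with zero runs omitted.

## Simulator

The synthetic locus defaults to exon1/intron/exon2 lengths of 500/2000/500
bp with a 300-bp pseudo-exon starting 100 bp into the intron — the same
shape as the motivating event (a multi-kb intron 1 whose pseudo-exon sits
near the donor) at a size where exhaustive enumeration is instant. Three
isoforms are expressed: canonical (exon1–exon2), mis-spliced
(exon1–pseudo-exon) and unspliced pre-mRNA, mixed as (1−f−r, f, r).

Reads are error-free 150-bp alignments (paired by default) — the artifact
tests counting logic, not an aligner — so classifier truth labels are exact
and boundary recoveries (PSI of exactly 0 or 1) are deterministic. Paired
fragments draw an integer length from a discretised truncated normal (mean
300, SD 50 — typical short-insert cDNA libraries) restricted to
[read_len, transcript length], then a uniform placement; one record is
emitted per mate, and `n_reads` counts records. Single-end reads place
uniformly over valid starts. All randomness flows from a single seed
through a fixed stream order (isoform draws, then per-isoform fragment
lengths, then placements), making output byte-reproducible.

`expected_psi` computes category probabilities per emitted record *exactly*
by enumerating every (isoform, fragment length, placement) combination,
classifying each template read with the production classifier and weighting
by mixture, fragment-length mass and uniform placement (prefix sums make
this O(transcript length) per fragment length). The per-read truth labels
written alongside simulated reads come instead from independent coordinate
arithmetic on the transcript, so the simulator and the classifier are
mutually checking rather than sharing a code path.

What the simulator does *not* model: sequencing errors, soft-clipping,
alignment ambiguity, positional or GC bias, and expression beyond the
three-isoform mixture. Passing recovery tests therefore demonstrates that
the counting and estimation machinery is correct under ideal alignments,
not that any aligner's output at a repeat-dense locus is unbiased.

## Test design and problem sizes

The recovery test grid covers mis-spliced fractions {0, 0.1, 0.5, 0.9}
crossed with retained fractions {0, 0.2} (capped so the mixture stays a
probability vector), 20 seeds per setting at 10,000 reads, requiring the
pooled PSI within 3 binomial standard errors of the enumerated expectation
in at least 19 of 20 seeds. That test uses single-end reads because the
binomial SE presumes independent record labels, which paired mates from one
fragment violate (their labels are positively correlated); paired mode is
exercised wherever no SE bound is involved. Fisher agreement is verified
exhaustively against an independent exact enumeration (via the
transposed-margin hypergeometric identity) for every 2×2 table with grand
total ≤ 100. The group-contrast experiment and the acceptance script use
four replicates of ~5,000 informative reads per group — large enough that
a 60% mis-splicing mixture separates from control by hundreds of standard
errors, small enough to run in seconds.

## Degenerate inputs and numeric conventions

Header-only alignment files yield all-zero counts, `NA` metrics and exit
status 0. An all-zero contingency table and a comparison with fewer than
two groups are contract errors. Interval arithmetic is 0-based half-open
everywhere internally; config files and SAM positions are converted at the
boundary, and normalize/denormalize round-trip exactly. Chromosome names
are matched after stripping an optional `chr` prefix unless strict mode is
set. The run manifest records tool version, settings, input digests, seed
and a wall-clock timestamp; the timestamp is the only run-specific output
field.

## Known limitations

Exactly one two-exon event per config (no GFF gene models); no CRAM; no
EM-style isoform abundance estimation or genome-wide intron-retention scan;
no beta-binomial/GLM modelling of replicate overdispersion — the Fisher
test treats pooled counts as one draw, which is anticonservative if
replicates are overdispersed (the reported per-replicate SD is the guard);
PSI from short reads at a CGG-repeat-adjacent locus inherits whatever
mapping bias the upstream aligner has, which the simulator deliberately
does not model.
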
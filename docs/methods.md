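# Methods

## Signal model and coordinates

A CTSS (CAGE tag start site) is a single base pair on one strand with a
positive tag count: the number of sequenced 5' ends of capped transcripts
mapping there in one sample. All internal coordinates are 0-based
half-open; GFF3 input/output is converted at the boundary. The 5'-end
convention (a minus-strand read's 5' end is its rightmost base) is assumed
already applied by the upstream mapper, since the inputs are per-strand
5'-coverage tracks. Input tracks must carry **raw counts**, not
pre-normalized values; normalization to CTPM (`count x 1e6 /
library_size`) happens inside the package, with `library_size` taken from
the sample sheet because it means *total mapped tags* — a superset of the
tags stored at retained positions — and cannot be recomputed from a track.

## Cluster calling

**Unidirectional (TSS).** On each strand independently, sorted nonzero
positions are split wherever the distance to the next position exceeds
`merge_dist` (default 20 bp, the scale of tag scatter around a core
promoter). Each run becomes one cluster spanning first to last member
position + 1; the peak is the member with maximal pooled CTPM, ties broken
toward the strand's 5' side so output is deterministic. This is exactly
the sort-and-split-on-gap procedure, and the test suite verifies it
against an independent brute-force oracle on 1,000 random signals.

**Bidirectional (enhancer).** Divergent eRNA transcription shows up as
minus-strand signal just upstream and plus-strand signal just downstream
of a midpoint. For a candidate midpoint m with windowed CTPM sums
M_U (minus in [m−r, m)), P_D (plus in (m, m+r]), and their wrong-side
counterparts P_U, M_D, the balance score is the Bhattacharyya coefficient
between the observed arm proportions and the ideal divergent profile:

    score = sqrt(0.5 * M_U / T) + sqrt(0.5 * P_D / T),   T = M_U+P_D+P_U+M_D

Score 1 means perfectly balanced divergence; signal on a single strand
caps the score at sqrt(0.5) ≈ 0.707, well below the default threshold
0.95 (which tolerates arm imbalance down to roughly 1:9). The score is
scale-invariant, so strong and weak enhancers are treated alike.

Every base within the signal's extent is scored (vectorized with
cumulative sums). Candidates at or above the threshold are resolved by
greedy non-maximum suppression: take the best-scoring midpoint (ties:
middle of the first tied run), emit it, suppress candidates whose ±r
windows would overlap it (closer than 2r), repeat. Plain
merge-of-overlapping-windows was tried first and rejected: chains of
weak candidates can bridge two distinct loci more than 2r apart, so a
spurious but perfectly balanced noise pair could swallow a genuine
enhancer 1–2 kb away. The cluster span is trimmed to the outermost
nonzero position (either strand) within the chosen window; spans wider
than `max_span` (1,000 bp) are discarded, and a caller-supplied TSS mask
can veto enhancers overlapping TSS cluster spans.

The window radius defaults to 500 bp. A radius of 400 bp cannot see both
arms of a divergent pair separated by more than ~800 bp, while enhancer
arm pairs in this data regime sit 400–1,000 bp apart; 500 bp covers
separations up to ~990 bp and keeps spans within the 1 kb cap.

**Quantification and filtering.** Each cluster's per-sample CTPM is the
sample's tag sum over the span (strand-matched for TSS, both strands for
enhancers) scaled by 1e6/library_size. A sample *supports* a cluster if
it has ≥ 1 raw tag in the span — the simplest reading of sample support,
independent of library size. Filtering keeps clusters with pooled count
≥ `min_pooled_count` (default 10) **and** support ≥ `min_samples`.
`min_samples` is always an explicit count, never derived from a fraction:
fractional rules ("2/3 of samples") round ambiguously, so the caller
states the integer (8 of the 12-sample default design). Filtering runs
after quantification so support reflects final spans. The stretch stage
applies only the pooled-count filter — enhancer activity is inherently
tissue restricted, so demanding pervasiveness there would discard exactly
the biology the scan targets.

## Annotation

Clusters are anchored on a single base (TSS peak; enhancer midpoint) so
each gets exactly one category, tested in fixed order: promoter (within
±100 bp of a same-strand transcript start), proximal (≤ 1 kb upstream of
one), then 5'UTR / 3'UTR / CDS / exon overlap, intron (inside a
transcript span), antisense (opposite-strand gene overlap only), else
intergenic. The ±100 bp promoter and 1 kb proximal windows are
configurable; 1 kb matches the conventional "proximal promoter" reach.
Strandless enhancers are tested against both strands and can therefore
never be antisense. Gene assignment searches gene spans extended 1 kb
upstream (same strand for TSS, either for enhancers), breaking multi-gene
ties by nearest transcript start; unassigned clusters receive
`NOVELG%06d` ids minted in genome order, making re-annotation idempotent.

## Coexpression links

All enhancer/TSS pairs on one chromosome with edge-to-edge gap ≤ 10 kb
are tested with Kendall's tau-b (tie-corrected, two-sided p from the
tie-adjusted normal approximation; constant rows are flagged untestable
and excluded rather than emitted as NaN). BH adjustment runs over all
tested pairs; retained links satisfy both p < 0.05 and q < 0.01 — the
double criterion is kept although the FDR cut dominates, mirroring the
standard procedure. Links are classed *novel* when neither endpoint has a
non-novel gene id, otherwise *cis* (gap < 1 kb) or *trans*; because
conventions differ on partially annotated pairs, an `either_novel` flag
is emitted alongside. A signed gap (negative = enhancer upstream of the
TSS on the TSS strand) supports orientation analyses, and the gap-vs-tau
landscape can be summarized by a product-Gaussian 2-D KDE with per-axis
normal-reference bandwidths (sigma · n^(−1/6)). Note that a TSS cluster
that *is* an enhancer's own arm correlates with that enhancer by
construction (they share tags); such gap-0 links are genuine outputs of
the procedure and dominate retained links at small sample counts.

## Stretches

Superenhancer stretches are maximal chains of enhancers whose successive
midpoint-to-midpoint gaps are ≤ 10 kb, keeping chains of ≥ 3 members —
the simplest maximal-chain reading of a 10-kb window scan (edge-to-edge
gaps available via a flag). Maximal chains are disjoint, so stretch
membership is a partition. Each stretch is scored by the mean Kendall
tau-b over all member pairs' expression rows; whether "mean correlation"
should aggregate pairs differently is genuinely open, so the pairwise
mean is used and labeled as such.

## Tissue, population and species specificity

The tissue profile of a cluster is f_t = mean_t / Σ_u mean_u over
per-tissue mean CTPM — tissue means first, so unbalanced replicate counts
do not skew the profile — and the scalar TSI is max_t f_t (1/T for
uniform expression, 1 for exclusive). The per-tissue fraction was chosen
over entropy- or max-ratio-style indices because it reads directly as
"share of expression in this tissue" on a 0–1 scale per tissue.
Per-tissue cluster calling reruns the full clustering stage on one
tissue's samples with relaxed support (min(2, n_samples)).

Per-population calling demands 100% within-population support. Signature
classes intersect the per-population sets: exact
(chrom, start, end, strand) matching by default, with a ≥ 1 bp
same-strand overlap rule (transitive, union-find components) available
because cluster boundaries jitter between runs on real data. All 2^k − 1
intersection classes are computed and reported; classes are provably
disjoint and cover the union. With exact matching on independent noisy
runs most regions fall in single-population classes — overlap matching is
the right choice when comparing real populations.

Cross-species comparison reduces each species to its set of TSS-bearing
gene symbols (uppercase-normalized, no paralog or synonym resolution) and
classifies each symbol in the union as avian/mammalian (all species),
mammalian-specific (all but the avian outgroup), human-specific (focal
set only), species-specific:<name> (exactly one non-focal species), or
partial-shared — an explicit residual class, because the four named
groups do not cover all sharing patterns.

## Synthetic data generator

The generator emulates a multi-tissue, multi-population CAGE study at
desk scale. Defaults: 2 chromosomes × 1 Mb, 200 genes, 12 samples (4
tissues × 3 populations), library size 1e6 (so one tag = one CTPM unit),
60 enhancers of which 30 are linked to a TSS, 3 three-enhancer stretches,
2 two-enhancer decoys, 8 tissue-private and 6 population-private TSS, and
uniform background noise of 30 singleton tags/Mb/sample. These sizes run
the whole pipeline in seconds while leaving every stage a nontrivial
recovery problem.

*Counts.* A TSS's per-sample tags are negative binomial (size 10) around
`nb_mean = 20` modulated by a per-tissue lognormal effect (sd 0.4) and a
per-sample lognormal latent factor (sd 1.2 — roughly a 3-fold typical
swing, matching the strong between-sample variability of CAGE
expression). Tags spread around the dominant base with geometric decay
(0.35/bp, ±10 bp), so the dominant base carries ~45% of the mass.
Enhancers emit a minus arm left and a plus arm right of their midpoint
(arm mean 15, mild lognormal asymmetry sd 0.15), separated by
U(400, 950) bp — within the 400–1,000 bp divergent-pair band, with the
upper end chosen so trimmed spans stay under the 1 kb cap once ±5 bp arm
spread is added.

*Coupling.* A linked enhancer–TSS pair shares a per-sample standard
normal factor with loading sqrt(rho) each, so their latent activities
correlate at exactly rho while staying marginally standard; the
observable Kendall tau rises monotonically in rho but is attenuated by
count noise — a recoverable, non-degenerate target. Private clusters
have structural-zero activity outside their tissue/population.

*Layout.* Blocks (plain genes, gene+enhancer linked pairs, stretches,
decoys, isolated enhancers) are placed sequentially with a 13 kb margin
after every enhancer-bearing block, guaranteeing by construction that no
unintended enhancer chain (> 10 kb rule) arises and that planted stretch
membership is unambiguous. Infeasible layouts fail before any sampling.
Everything is deterministic under a fixed seed, down to byte-identical
bedGraph output.

*What is not emulated:* mapping biases, the CAGE G-addition artifact,
promoter shape classes (broad vs sharp), correlated replicate structure
within tissues beyond the tissue effect, and realistic gene density.
Passing recovery tests on this generator therefore demonstrates the
correctness of the calling/statistics machinery under the stated noise
model, not performance on real libraries.

## Numerical choices and edge cases

* Balance threshold comparisons use a 1e-12 tolerance; peak and midpoint
  ties break deterministically (5'-most peak; middle of the first tied
  candidate run).
* Zero-expression clusters get a `zero_flag` and all-zero TSI fractions
  rather than NaN; constant expression rows yield a flagged no-test
  result in Kendall testing, never NaN in output files.
* The KDE refuses zero-variance axes and suggests jittering instead of
  silently degenerating.
* BED output requires (chrom, start)-sorted input and errors rather than
  silently sorting; enhancer BED6 intentionally drops the midpoint (BED
  has no field for it) while coordinates, strand and peak round-trip.
* Empty categories serialize as header-only files; truth tables use the
  same 0-based convention as BED so joins are coordinate-exact.

## Known limitations

* At small sample counts (the 12-sample default) the link test has
  limited power for moderate latent correlation; the power and
  error-control guarantees are stated and verified at a 24-sample pair
  design.
* Exact-coordinate population matching understates sharing on noisy data
  (see above); this is inherent to the rule, not the implementation.
* Symbol-based species comparison misses paralogs and synonym renames by
  design.
* The per-gene TSS multiplicity summary depends on real promoter
  architecture and is reported, not calibrated.
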
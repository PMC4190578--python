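# Methods

## The measurement model

DGE tag profiling reduces each transcript to its NlaIII-anchored 21-nt
tags: a `CATG` anchor plus the 17 following bases. Libraries are tables
of tag sequences and counts; expression for a gene is the sum of counts
of its unambiguous tags, scaled to tags per million (TPM). The analysis
therefore has three statistical layers — tag-level (database building,
cleaning, mapping), count-level (exact two-library testing), and
profile-level (clustering, enrichment, segment mining) — each implemented
as one package module.

## Synthetic data generator

The generator emulates the structure of a 24-library CSIL study: six
lines (five introgression lines plus the recurrent parent TM-1) × four
fiber-elongation stages (5–20 days post-anthesis), one library per
line × stage.

**Reference.** Transcripts are i.i.d. uniform nucleotide sequences
(default 2,000 genes, 300–2,000 nt). A Bernoulli(0.02) subset is
guaranteed to contain no `CATG` (exercising tagless-gene handling);
every other gene is guaranteed at least one anchored tag. A fraction of
genes (default 0.30) is generated as a low-divergence copy (1% per-base
substitution) of another gene. This paralog model is the mechanism behind
the roughly-half unambiguous mapping rate characteristic of DGE libraries
built on a diploid reference for a polyploid-derived sample: tags shared
between a gene and its copy are genuinely ambiguous and are excluded at
mapping, yielding ~50–60% unambiguous mapping under the defaults.

**True expression.** Baseline relative abundances are log-normal
(meanlog 0, sdlog 1.5), heavy-tailed as real tag-count distributions are,
and shared across libraries. For each non-parent line × stage, 10% of
genes receive a planted log₂ fold change of ±2 (balanced signs keep the
renormalization shift small). Half of each library's DE picks come from a
per-stage pool shared by all lines with a common sign — emulating
stage-driven responses common to all introgression lines, which is what
makes common-DEG sets non-empty — and half are private to the line.
Columns are renormalized to sum to 1; the planted log₂ fold changes are
recorded as ground truth.

**Tag libraries.** Each library draws `depth` tags (default 10⁵ at desk
scale; the emulated study depth is 7.0–8.7 M): the gene by true
abundance, the tag position within the gene by a geometric 3′ bias
(weight 0.8 on the 3′-most anchor, reflecting NlaIII DGE chemistry), then
independent per-base substitution errors (default 1%, uniform over the
three alternatives, no indels since tags are fixed-length). A 1% fraction
of tags is truncated to 12–20 nt (short-tag contamination) and 0.5% is
replaced by random unique 21-mers (junk singletons). Replacement rather
than injection preserves the exact conservation invariant: counts always
sum to `depth`. Singletons also arise naturally from sequencing errors.

**Determinism.** Every operation is deterministic for a fixed seed.
Per-library streams are keyed on (master seed, CRC32 of the library id),
so libraries can be regenerated independently and in any order, and a
rerun of the pipeline under the same configuration is byte-identical.

**What the generator does not model.** Read-level artifacts (quality
scores, adapters, base-caller bias), biological replicates (the emulated
design has one library per condition), correlated expression programs
across stages, and real annotation structure (terms and pathways are
random). Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated statistical model, not
performance on any particular real dataset.

## Tag database and mapping

All `CATG` positions per transcript are indexed, not only the 3′-most,
because gene expression is summed over tags at different positions of the
same gene; sense strand only by default (the reference is a transcript
set), with antisense indexing behind a flag. Cleaning removes tags
shorter than 21 nt first, then singletons — defined at tag level (a tag
whose library-wide count is 1) since the input is a tag-count table.

Mapping is tiered: exact hits take precedence over Hamming-distance-1
hits, and ambiguity is evaluated within the winning tier only. A tag
ambiguous at distance 0 stays excluded even if some distance-1
interpretation would be unique; exact-first maximizes specificity. The
1-mismatch search enumerates the 63 single-substitution variants per tag
against the hash index; its contract (verified in tests) is tag-for-tag
agreement with a brute-force all-pairs Hamming scan. The count partition
`mapped + ambiguous_excluded + unmapped = clean_total` holds exactly for
every library.

## Differential expression

TPM uses unambiguously mapped tags as the denominator, so TPM sums to 10⁶
over genes within each library.

The two-library exact test conditions on the observed count *x*: under a
common Poisson rate, the count *y* in the second library given *x*
follows P(y|x) = (N₂/N₁)ʸ (x+y)!/(x!·y!·(1+N₂/N₁)^(x+y+1)), which is the
negative binomial NB(r = x+1, p = N₁/(N₁+N₂)). Tails are evaluated
through the scipy negative-binomial CDF/SF (log-space internally); both
tails include the observed y and the two-sided p doubles the smaller
tail, clipped to (0, 1]. The doubled-tail p is *orientation-dependent*:
swapping (x, N₁) with (y, N₂) changes the conditioning variable, and the
two orientations agree only approximately (well within an order of
magnitude at moderate significance, diverging somewhat in deep tails).
The pipeline always conditions on the parent library, making every
comparison internally consistent.

FDR control is Benjamini–Hochberg step-up per comparison (each comparison
is its own family, since calls are thresholded per comparison). Genes
with x = y = 0 are excluded from testing and from the BH family. DEG
calls require q ≤ 0.001 and |log₂ ratio| ≥ 1; the log₂ ratio is computed
on TPM with a one-tag pseudo-TPM offset (10⁶/N per library) added to both
numerator and denominator so zero counts stay finite, while the p-value
uses raw counts (the exact test handles zeros natively).

Under null simulations (identical abundances, 2,000 genes, depth 10⁶,
20 replicates) the DE-call fraction is far below the nominal 0.002;
with 10% planted |log₂fc| = 2 genes, sensitivity exceeds 0.9 for genes
with baseline TPM ≥ 20 and the empirical FDR among calls stays below
0.05 (both measured by the acceptance script).

Common-DEG set logic is plain set algebra over per-line call tables at a
stage: intersection, up-in-all, and down-only-in-one-line (optionally
requiring up in every other line). The cross-platform validation
correlation is squared Pearson r on log₂(v+1)-transformed values by
default (raw scale behind a flag), mirroring how sequencing TPM is
compared against qRT-PCR 2^(−ΔCT) relative quantities.

## Clustering

Genes expressed (TPM > 0) in strictly more than half of the libraries
are retained and log₂(TPM+1)-transformed — the +1 offset avoids −∞ at
zero and is the conventional choice when the transform is otherwise
unspecified. The library-level Pearson matrix is computed on these
profiles.

SOTA is implemented from the published algorithm (the study used it
through a GUI tool whose parameterization is unrecorded, so defaults are
exposed in full): a binary tree starts as a root with two leaf children;
profiles are presented cyclically in row order; the winning leaf adapts
its centroid toward the profile (rate 0.01), and when its sister is also
a leaf, the sister (0.001) and parent (0.005) adapt too; when the
epoch-to-epoch error stabilizes, the leaf with the highest *resource*
(mean member-to-centroid distance) splits, until `max_clusters` leaves
(default 5, mirroring four expression groups plus an unclassified bucket
at the profile level; 6 for DEG grouping) or until every resource falls
below threshold. Distance is correlation-based: profiles are row-centered
and L2-normalized so 1−r equals half the squared Euclidean distance; on
that sphere the optimal centroid of a member set is its normalized mean,
and each growth cycle ends with exact centroid refinement, which makes
the recorded total resource non-increasing across cycles. Ties break
toward the earliest-created leaf; jitter at splits comes from the seeded
generator, so runs are fully deterministic.

DEG expression groups (the G1–G6-style cut) use average-linkage
hierarchical clustering on 1−r distances via scipy, cut to k groups; an
independently hand-coded O(n³) agglomerator verifies the merges on small
instances in the tests.

## Enrichment

Annotations are closed under the term DAG before testing (true-path
rule), implemented as ancestor closure over child→parent edges; the
closure is idempotent and monotone, and cycles are rejected naming a
member. The test is the one-sided upper-tail hypergeometric
P(X ≥ k) for k study hits among n study genes, against K annotated genes
of N background genes; terms are tested only when k ≥ 1 and K ≥ 2
(untestable or uninformative terms are skipped). BH correction runs
across all tested terms within one run; results are ranked by (q, p) and
flagged enriched at q ≤ 0.05. Pathway enrichment is the same test plus
the rich factor k/K. The default background is all genes expressed in the
libraries under comparison (the full reference is available by flag) —
with no stated convention, the expressed universe is the defensible
choice because unexpressed genes cannot be called differential.
Underflowed p-values are clipped to 10⁻³⁰⁰ to keep the BH input valid.

## Segment mining

Coordinates are 1-based fully-closed in all TSV interfaces; overlap means
any shared base, and strand is ignored (segment introgression is
strand-agnostic). Candidates are segment genes called in the requested
direction (default up) in at least one stage of the segment line's
comparisons, reported with their per-stage call profile, then handed to
the enrichment module against the expressed background.

## Problem sizes and numerical choices

Desk-scale defaults — 2,000 genes, depth 10⁵, 6 lines × 4 stages —
exercise every code path in seconds per stage while preserving the
statistical regime of interest (mapping rate near one half, tens of DEGs
per comparison); calibration and power experiments use depth 10⁶ and
20 replicates at the gene-count level. The full study scale (37,505
genes, 7.0–8.7 M tags per library) is plain configuration.

Tolerances: exact-test implementation vs direct-summation oracle agrees
to <10⁻¹⁰ over the tested grid; TPM column sums hold to 10⁻⁶; BH matches
an independent implementation to 10⁻¹²; hypergeometric p matches exact
rational arithmetic to 10⁻¹² for N ≤ 60. Tie-breaks everywhere resolve
toward the lowest index for determinism.

## Known limitations

- One library per condition: no replicate-aware dispersion modeling; the
  exact test assumes Poisson sampling within a library, so biological
  variability between plants is not separated from sampling noise.
- The doubled-tail exact p is orientation-dependent (see above); the
  parent is always the conditioning library.
- SOTA recovery guarantees hold for well-separated planted structure;
  strongly overlapping expression programs can split across leaves.
- The synthetic annotation/pathway maps are random, so enrichment runs on
  pipeline output demonstrate plumbing and calibration, not biological
  signal; planted-enrichment tests inject signal explicitly.
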
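# Methods

This note documents the models implemented in `tilseq`, the assumptions
behind them, every numerical choice that was genuinely open, and what
the synthetic-data validation does and does not establish.

## Hashtag demultiplexing

Cell hashing labels each sample with a DNA-barcoded antibody before
pooling, so a cell's hashtag-count vector identifies its sample of
origin. The demultiplexer treats the per-cell tag counts as a
composition and works on the centered log-ratio scale:

    clr(c, h) = ln(n_ch + 1) − (1/k) Σ_h' ln(n_ch' + 1)

computed within each cell across its k hashtags (pseudocount 1). The
margin and pseudocount are choices of this implementation: row-wise CLR
matches the compositional reading of per-cell tag counts, and the unit
pseudocount keeps zero counts finite without distorting large ones.

Cells are then clustered with PAM k-medoids, k equal to the number of
hashtags, Euclidean distance on CLR profiles, deterministic BUILD
initialization and steepest-descent swaps — so a fixed input always
produces the same local optimum, and the objective never increases
across swaps. Each cluster's dominant hashtag is the one with the
highest mean CLR among its cells; if two clusters share a dominant
hashtag a degeneracy warning is recorded and the more permissive
(smaller) threshold candidate is used.

The positivity threshold for a hashtag is the lowest CLR value of that
hashtag among its cluster's cells. Because a straggler can sit far below
the cluster body, the minimum is tested with a one-sided Grubbs outlier
test at α = 0.05,

    G = (mean − min) / s,
    G_crit = ((N−1)/√N) · √(t² / (N−2+t²)),  t = t-quantile(1 − α/N, N−2),

and removed-and-retested until the surviving minimum is no longer
significant. Clusters of fewer than 3 cells skip the test (it is
undefined) and use the raw minimum. A cell at or above the threshold is
positive for that hashtag (the threshold value belongs to a member
cell, which is positive by construction); exactly one positive flag
makes a singlet, several a doublet, none a negative. All steps run
independently per array so depth differences never pool.

**Known limitation — masking.** The iterative test examines one extreme
value at a time. Several stacked low values inflate the sample SD enough
that none is individually significant (e.g. two values near −3 among
eight near 2 give G = 1.94 < G_crit = 2.18 at N = 10), and the loop then
stops with the contaminated minimum as threshold. This is inherent to
iterated single-outlier Grubbs; it is why the procedure assumes clusters
that are mostly pure, and why manual threshold overrides are exposed
(`demux --override HTO=value`).

## TCR assembly

Reads tagged (cell barcode, UMI, chain, sequence) are aggregated per
(barcode, chain, UMI); groups under 5 reads are discarded. Within a
group, equal-length sequences are single-linkage clustered at Hamming
distance ≤ 2 (unequal lengths are never linked — the simplest
operationalization of "sets of similar sequences"); the largest set
qualifies only if it holds strictly more than 90% of the group's reads,
the share being computed over reads, not distinct sequences. The
consensus is the read-weighted majority base per position, ties going to
the alphabetically smallest base.

Directional UMI collapse then repairs PCR/sequencing errors in the UMI
itself: an edge a → b exists when the UMIs differ at exactly one
position and reads(a) ≥ 2·reads(b) − 1; components are grown
breadth-first from the highest-count node, walking only from higher to
lower counts, and collapse into their seed with read and UMI counts
summed. The pass is **iterated to a fixed point**: absorbing a child
raises the seed's count, which can license a merge the original counts
forbade, and a one-shot pass would therefore not be idempotent.
Idempotence was chosen as the governing contract; the difference from a
one-shot pass arises only in such cascade corner cases.

Per cell and chain, collapsed records are aggregated by consensus
sequence — a candidate sequence's UMI count is the number of corrected
molecules supporting it — and the candidate with the most UMIs, then
most reads, then the alphabetically smallest sequence is retained. CDR3
amino-acid annotation is consumed from the read table (germline V/J
alignment is upstream of this package); records without a CDR3 are
dropped, and cells with neither chain are omitted. Every tie-break in
the chain is deterministic, so output is invariant to read order.

## Specificity annotation

The reference is built from tetramer-sorted CD8⁺ T-cell clonotypes
against the p15E retroviral envelope epitope. For each CDR3 amino-acid
sequence — β and α evaluated independently, with cell counts pooled
across clonotypes sharing the CDR3 — inclusion requires detection in at
least 2 cells and a tetramer-positive cell fraction strictly greater
than 0.8. Whether the source analysis counted cells or UMIs is not
determinable; cells are used. A query clonotype is p15E-specific when
its CDR3β is in the β reference, its CDR3α in the α reference, or its
CDR3α contains `DYSNNRLT` as a contiguous substring ("utilized the
motif" is read as substring containment). Match precedence
β > α > motif affects only the reported evidence, never the label.

## Expression scoring

QC removes cells with fewer than 500 detected genes, then genes detected
in fewer than 5 remaining cells, iterating the gene filter to a fixed
point (one pass already is one — removing a gene changes no other gene's
cell count — the loop documents the contract). Normalization is
ln(1 + count/total × 10⁴) per cell; the scale factor and natural log
with unit pseudocount are conventional choices. Variable genes require
mean normalized expression > 0.1 and dispersion (variance/mean of
normalized values, without within-bin z-scoring) > 1, both strict.

The cytotoxicity score uses the granzyme signature (Gzma, Gzmb, Gzmc,
Gzmd, Gzme, Gzmf, Gzmg, Gzmk, Gzmm). All genes are ranked by mean
normalized expression (ties broken by name) and cut into 24
equal-frequency bins; each signature gene draws 100 control genes
uniformly with replacement from its bin under a fixed seed; the score is
the mean signature value minus the single pooled control mean, per cell.
Bin count and control count follow the published description of
expression-binned module scoring; signature genes are not excluded from
the control pool. Consequences: the score is exactly invariant to adding
a constant to one cell's profile, reproducible under a fixed seed, and
centered near zero for cells without a granzyme program. Cells with no
recovered TCR chain are excluded from the cytotoxicity analysis; bins
and control draws are computed on the full matrix so a cell's score does
not depend on which other cells carry TCRs.

## Statistics

The two-sided Wilcoxon rank-sum test uses the exact null distribution of
the rank sum when both samples have ≤ 10 observations and no ties are
present, otherwise the normal approximation with tie-corrected variance
and continuity correction (scipy's Mann–Whitney machinery stands behind
this surface; an independent full-enumeration oracle checks it in the
tests). Per-gene differential expression applies this test to
log-normalized values with Bonferroni adjustment by default
(Benjamini–Hochberg by flag); the effect size reported is the
difference of group means of log-normalized values — a deliberate,
simpler substitute for a ratio-based fold change, sufficient for
ranking. Relative body weight is
(BW_x/BW_0)/(BWctrl_x/BWctrl_0) against the control-group mean
trajectory.

## Synthetic data: what it emulates, and what it does not

All generators draw from named substreams of one top-level seed
(`SeedSequence` keyed by generator name), so outputs are bit-identical
under a fixed seed and adding a generator never perturbs another.
Negative binomial counts are parameterized by (mean m, dispersion r)
with variance m + m²/r.

**Hashing arrays.** One sample per hashtag, 200 cells each by default.
Singlets draw NB(signal) on their own hashtag and NB(background) on the
rest; doublets draw full NB(signal) on two distinct hashtags (signal not
halved — a deliberate, conservative choice that makes doublets
detectable by design); negatives draw background everywhere. Defaults:
signal mean 200, background mean 5, doublet rate 5%, negative rate 1%,
dispersion 4.5. The noise level and negative rate are calibrated to the
separability structure the thresholding method assumes: on the CLR
scale a doublet's on-target value sits ≈ (ln s − ln b)/k below a
singlet's, so thresholds (≈ 3 SD below the singlet mean) discriminate
doublets only when the signal log-scale SD is ≥ ~0.42 — a count CV near
0.5, typical of real hashing libraries — while the iterated Grubbs
tolerates only a small per-cluster contingent of negatives before
masking sets in, consistent with FACS-sorted, antibody-stained input
where unhashed cells are rare. Real arrays additionally contain ambient
tag soup, saturation and batch effects, which are deliberately not
modeled; recovery rates measured here characterize the method under its
own assumptions, not performance on arbitrary real data.

**TCR reads.** Clonotypes receive random in-frame nucleotide sequences
(30–60 nt) and CDR3 amino-acid strings; a configurable fraction embeds
the `DYSNNRLT` motif in CDR3α. Cells per clonotype, UMIs per chain and
reads per UMI are fixed integers rather than distributions so the truth
table is exact; sequencing noise is per-base substitution at a given
rate, and a configurable fraction of UMIs gains a one-mismatch duplicate
UMI carrying ⌈r/2⌉ reads, which satisfies the 2n−1 merge rule by
construction. No V(D)J recombination model is implied.

**Expression.** Genes × cells NB counts with per-gene means drawn
lognormal(0, 1) and dispersion 2; cytotoxic-group cells multiply the
granzyme-gene means by exp(shift), 1 log-unit by default; all other
genes are exchangeable between groups. **Tetramer reference.** Each
clonotype gets 1 + Poisson(3) cells and a latent tetramer-positive
propensity uniform on [0, 1]; realized positive counts are binomial, and
the truth label applies the reference rule to the realized counts.

## Validation sizes and numerical tolerances

Demultiplexing recovery is measured over 20 arrays (~22,000 cells);
consensus accuracy over 10 read simulations (~5,700 retained UMIs);
collapse against a brute-force oracle on 1,000 random instances of up to
12 UMIs; the module-score null over 100 replicates of 200 cells × 300
genes and the effect arm over 20 simulations of 1,000 cells × 1,000
genes; rank-sum exactness over all 64 sample-size pairs with n ≤ 8 by
full enumeration, and the type-I error over 10,000 null draws at
n = 20/group. CLR row sums are required to vanish to 1e−9; the Grubbs
closed form must match an independent t-quantile evaluation to 1e−6;
exact rank-sum p-values match enumeration to 1e−12. These sizes are the
package's validation conditions; the acceptance script re-derives all of
them from scratch under a user-supplied seed.
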
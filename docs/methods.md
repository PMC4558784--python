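# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the places where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Normalization

Library size N_k is the raw column total (a zero total is a hard
error). TMM factors are computed per sample k against a reference r —
the sample whose 75th percentile of library-scaled values is closest to
the mean 75th percentile, the standard convention. Over genes positive
in both samples:

    M_g = log2((y_gk/N_k)/(y_gr/N_r))
    A_g = 1/2 log2((y_gk/N_k)(y_gr/N_r))
    w_g = (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr)

The top and bottom 30 % of genes by M and 5 % by A are dropped (rank
trim with stable tie-break by gene index), and the factor is
2^(Σ w_g M_g / Σ w_g) over the survivors, then all factors are rescaled
to geometric mean 1 (asserted to 1e−9). We define the weighted mean
with w as written above; this package treats that formula as the
definition of its TMM step, and the test suite checks it against an
independent brute-force implementation to 1e−10. Fewer than 10
surviving genes yields factor 1 with a warning. Trim fractions, the
pseudo-value and the reference sample are exposed as parameters.

A consequence worth knowing: M- and A-values depend only on y/N, so
rescaling a column changes no trimming decision, but w carries a 1/N_k
term, so the weighted mean — and hence the factors — move slightly
(relative ~1e−3 for an 8× rescale). The property test asserts the exact
part (trim sets) and a 1e−6-relative band on factors and signals.

Signals are log2 CPM: log2((y+c)/(N_k f_k + 2c) · 1e6) with prior
c = 0.5 raw units — strictly increasing in y and finite at y = 0.
Raw zeros are additionally re-expressed at the noise floor (the 1st
percentile of the matrix's nonzero raw values; a global percentile is
deterministic and easy to document) and flagged, so MA/volcano plots
can mark them with a cross and downstream ratios never divide by zero.
The percentile is a parameter.

## Differential expression

One-way NB GLM with log link and per-sample offsets log(N_k f_k);
variance μ + φμ². For a one-way layout the coefficient per group is a
scalar, fitted by Newton iterations with step halving; the
log-likelihood is asserted non-decreasing per iteration (equivalently,
deviance non-increasing). Below φ = 1e−8 the likelihood switches to the
Poisson limit. Log-likelihoods are computed up to the additive
constant −log Γ(y+1), which cancels in every ratio and argmax.

Common dispersion maximizes the sum over genes of the Cox–Reid adjusted
profile likelihood (the adjustment is −½ log of the per-group Fisher
information, diagonal here), on a log-scale grid over [1e−4, 4] refined
by golden-section to 1e−6. Tagwise dispersions maximize the per-gene
adjusted profile likelihood plus `prior_df` times the genes-averaged
shared likelihood (weighted-likelihood empirical Bayes), bounded in
[1e−6, 10]; the shared curve is splined from a 61-point grid and each
gene is refined by a vectorized golden-section. As prior_df → ∞ all
tagwise values collapse onto the common one (tested at 1e9 to 1e−4).
Default prior_df = 10. Note that the Cox–Reid adjustment leaves a
zero-variance gene with a tiny *interior* optimum (~5e−4) rather than
the numeric lower bound; "effectively zero" is the defensible property
and the one tested. Genes with zero total count are excluded from
dispersion estimation and inherit the common value.

Each contrast is a likelihood-ratio test: separate means for target and
control vs one pooled mean (all other condition levels cancel from the
ratio), referred to χ²(1). logFC is the difference of fitted group
log-CPMs divided by log 2, with each group's fitted CPM floored at the
noise-floor CPM so a group with all-zero counts yields a large finite
logFC instead of ±∞ — the "zeros scaled to noise level" rule carried
into the ratio. This keeps swap-antisymmetry exact (swapping target and
control negates logFC and preserves p to machine precision, tested).
The floor only binds for fitted CPMs below the 1st-percentile noise
level. FDR is Benjamini–Hochberg within each contrast (statsmodels).

Filters read the raw p-value by default with a `--use-fdr` switch; both
columns appear in every output table. Non-integer input units
(RPKM/FPKM/TPM) are rounded to the nearest integer for the NB
likelihood, with a logged warning — the statistical model needs counts,
and rounding makes the behavior defined rather than silently wrong.
Designs without any replicated condition are a hard error unless a
fixed dispersion is supplied.

Fold-change cutoffs are compared on the log2 scale with a 1e−12 slack
so that boundary cases (FC exactly 2 or 5) are inclusive despite
floating-point representation of log2(5).

## Global structure

The experiment correlation matrix is Pearson over TopHits-restricted
signals, rows/columns ordered by average-linkage clustering of 1−r;
zero-variance columns get r = 0 with a warning. MDS uses the leading
log-fold-change convention — the RMS of the 500 largest per-gene
|signal differences| per sample pair — followed by classical Torgerson
scaling to 2 centered dimensions; any 3-point metric embeds exactly
(tested to 1e−9).

K-means is Lloyd with k-means++ initialization, best of 10 restarts,
convergence at relative inertia change < 1e−6 or 300 iterations,
inertia asserted non-increasing per iteration, and an emptied cluster
re-seeded at the farthest point. It is implemented in-package rather
than via sklearn.KMeans because those iteration-level assertions, the
empty-cluster rule and exact seed-determinism are part of the contract;
silhouette scoring comes from scikit-learn. The number of clusters is
chosen automatically as the k in [2, 12] (truncated to rows−1)
maximizing mean silhouette, ties to the smallest k; under 4 rows the
rule degenerates to k = 2 with a warning. Mean silhouette was chosen
because it is deterministic, bounded and comparison-free across k — the
automation rule itself was an open design point. Hierarchical
clustering is scipy average linkage on 1−Pearson distances, checked
against a brute-force agglomerator on small instances.

Clustering feature spaces: "signal" = mean log2 CPM per condition,
"ratio" = logFC per contrast; rows restricted to TopHits (clustering
thousands of flat genes is noise), run for all genes and per class.

## Classes, plots, network

Per class: a members × conditions profile matrix (condition means in
signal space), a member–member Pearson correlation over those profiles,
and a heatmap row order from hierarchical clustering. A gene may belong
to several classes; plots need one color, so the first class listed in
the Classes file wins (full membership is kept in the tables).
Unclassed genes are black; zero-flagged genes are drawn as crosses.
Volcano y is −log10 of the raw p (or FDR with the global switch),
floored at 1e−300.

The overlap network has one node per contrast and one per TopHits gene,
an edge exactly when the gene passes the TopHits cutoffs in that
contrast, signed by logFC direction; the edge count therefore equals
the summed per-contrast up+down counts (asserted). The
Reingold–Tilford layout needs a tree, but the overlap graph has cycles;
genes with an identical contrast-membership signature are grouped under
an invisible signature node beneath the first contrast of their
signature, and the tidy-tree pass places each subtree by merging
per-depth contours with a minimum unit gap and centering every parent
on its extreme children (both properties tested on random trees to 200
nodes). Signature nodes and the virtual root are dropped from the
exported coordinates.

## Pipeline and determinism

The runner executes io → normalization → diffexp → genesets → structure
→ classnet, writes every declared TSV (floats at 6 significant digits),
optional PNGs, a run log with seed and version, an HTML index (stdlib
templating), a MANIFEST with a SHA-256 per file and a completeness
status, and a zip with fixed timestamps. One seed feeds every random
consumer; two runs with the same inputs and seed produce byte-identical
TSVs (tested). On any hard error the partial outputs remain and the
MANIFEST says INCOMPLETE.

## Synthetic data generator

The generator emulates a compact factorial prokaryotic experiment:
wild type plus four mutants, 2 replicates each (10 libraries), 2,000
genes, log-normal baseline abundances (ln-scale sd 1.5, heavy-tailed
like real transcriptomes), library sizes log-normal around 2×10⁶ reads
with CV 0.15, NB counts at φ = 0.1, and 10 % of genes per mutant spiked
at signed log2FC ±2. Half of each mutant's spiked genes form a
co-regulated, same-direction class (a regulon caricature) with a display
color. A graded variant instead up-regulates one shared 200-gene set
with |log2FC| growing {1.2, 1.6, 2.2, 3.0} across the mutant order, so
correlation matrices, TopHits counts and clustering can be checked for
gradient recovery. Everything is a deterministic function of the seed.

What it does not emulate: GC/length biases, batch effects, trended
(mean-dependent) dispersion, zero inflation beyond NB sampling, or
correlated genes outside the constructed classes. Passing tests
therefore demonstrate calibration and recovery under a clean NB world,
not robustness to those artifacts.

Problem sizes in the test suite (2,000 genes, 3+3 or 5×2 libraries, 50
random matrices for oracle comparisons, trees to 200 nodes) are the
package's desk-scale defaults: large enough for stable rates, small
enough to run interactively.

## Known limitations

- One-way model only; extra factor columns (e.g. Time) are annotations,
  not covariates. No quasi-likelihood F-test, no trended dispersion.
- Unreplicated designs require a user-supplied dispersion.
- The LRT with moderated tagwise dispersion is mildly liberal at very
  small replication, as the null simulation shows (~0.05–0.06 at 3+3).
- The noise floor is matrix-global; per-sample floors would differ for
  libraries of very unequal depth.
- scipy's linkage tie-breaking, not the smallest-index rule, decides
  exact ties in hierarchical clustering; random data makes ties
  measure-zero, and the brute-force comparison is on tie-free inputs.
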
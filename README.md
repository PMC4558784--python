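# trex-rnaseq

A statistical analysis pipeline for RNA-seq gene-expression tables,
aimed at biologists and bioinformaticians working on prokaryotic (or any
compact) transcriptomes. Starting from a genes × samples expression
table — raw counts, RPKM, FPKM, TPM or CPM — plus three small
tab-delimited design files, it produces normalized signals, per-contrast
differential-expression statistics, derived gene sets, global structure
views, per-regulon ("class") reports, MA/volcano plot tables and a
gene–contrast overlap network, all as plain TSV files plus static
figures and an HTML index.

## Model

Counts are modeled per gene *g* and sample *k* as negative binomial,

  y_gk ~ NB(μ_gk, φ_g),  Var(y) = μ + φμ²,

with a one-way GLM on the condition factor: log μ_gk = β_gj + log(N_k f_k),
where N_k is the library size and f_k the TMM scaling factor (trimmed,
weighted mean of per-gene log-ratios M_g against a reference sample,
rescaled to geometric mean 1). Signals are log₂ CPM with a small
pseudo-value; raw zeros are re-expressed at a global noise floor and
flagged, so ratios stay finite when a gene is absent from one condition.

Dispersion is estimated by maximizing the Cox–Reid adjusted profile
likelihood — a common φ over all genes, then tagwise φ_g shrunk toward
it by a `prior_df`-weighted shared likelihood (empirical Bayes). Each
declared contrast "Target-Control" is tested by a likelihood-ratio test
(χ², 1 df) of separate vs pooled group means; p-values get
Benjamini–Hochberg FDR within each contrast.

Derived gene sets follow fixed cutoffs over all contrasts: **TopHits**
(fold change ≥ 2 and p ≤ 0.05 in at least one contrast), **HighFold**
(FC ≥ 5, p ≤ 0.01), and **no_background** (everything except genes flat
in every contrast: FC ≤ 1.4 and p ≥ 0.25). Fold change is absolute, so
down-regulation counts symmetrically. Global structure is summarized by
a Pearson correlation matrix of experiments, classical (Torgerson) MDS
on leading log-fold-change distances, k-means with the cluster number
chosen automatically by mean silhouette, and average-linkage
hierarchical clustering on a 1−r distance — each run on both the
"signal" space (mean log₂ CPM per condition) and the "ratio" space
(logFC per contrast), for all TopHits genes and per class. Overlap
between any number of contrasts is shown as a bipartite gene–contrast
network (edge ⇔ the gene passes the TopHits cutoffs in that contrast)
laid out with the Reingold–Tilford tidy-tree algorithm and exported as
Cytoscape-importable node/edge tables.

## Worked example

Generate a synthetic five-condition experiment (wild type plus four
mutants, duplicate libraries, NB counts with φ = 0.1, 10 % of genes
spiked at |log₂FC| = 2) and analyze it:

```sh
trex simulate --out demo/in --seed 42 --n-genes 2000
trex run --data demo/in/expression.tsv --factors demo/in/factors.tsv \
         --contrasts demo/in/contrasts.tsv --classes demo/in/classes.tsv \
         --out demo/out --seed 42
# wrote 53 files to demo/out
```

The overview table of differential expression (`demo/out/updown_counts.tsv`):

```
contrast	total_genes	n_up	n_down	fc_cutoff	p_cutoff
A_F71Y-WT	2000	164	98	2	0.05
B_R61K-WT	2000	166	93	2	0.05
C_R61H-WT	2000	166	92	2	0.05
Null-WT	2000	169	94	2	0.05
```

Each contrast spikes 200 genes — about 150 up and 50 down, since the
half assigned to a regulon-style class share the upward direction — and
the counts above are those true positives recovered at high sensitivity
plus ≈ 5 % of the 1800 null genes splitting evenly between up and down. Per-contrast
tables (`Null_WT_results.tsv`) carry `gene, logFC, avg_signal, p_value,
fdr, zero_flag, class, color`; TMM factors land close to 1
(`tmm_factors.tsv`, e.g. WT_1 1.11337, Null_2 0.947691) because the
simulated libraries differ mostly in depth, not composition.

The Python API mirrors scikit-learn where the steps are
fit/transform-shaped:

```python
from trex import TMMNormalizer, NBDiffExp, read_expression_table

data = read_expression_table("demo/in/expression.tsv")
signal = TMMNormalizer().fit_transform(data)           # log2 CPM
de = NBDiffExp().fit(data.values, conditions)          # dispersions
res = de.test_contrast("Null", "WT").table             # logFC, p, FDR
```

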
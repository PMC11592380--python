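# Methods

This note documents the models, algorithms, and design decisions behind
each pipeline stage, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Synthetic cohorts and planted truth

`atheronet.synth` generates every input the pipeline consumes, with the
generating mechanism recorded as ground truth.

**Expression.** Genes live on a log2 scale. A co-expression module is a
single latent factor `f ~ N(0, 1)` per sample with equal loadings:
gene `g` in module `m` is `λ·f_m + ε`, `ε ~ N(0, σ²)` i.i.d. With
`λ = σ·sqrt(c/(1−c))` the population within-module correlation is exactly
the configured `c` (`module_cor`), so module strength is analytically
checkable rather than tuned. Differential expression is an additive shift
of `±de_log2fc` applied to the case arm, so the two-group mean difference
targets the planted value exactly; in the noiseless limit recovery is
exact. Batch effects are additive per-(gene, batch) `N(0, batch_sd²)`
offsets with samples assigned to batches round-robin (batch and group are
never confounded). When `de_in_modules` is set, module genes are made DE
first and each module's genes share one shift sign — a co-regulated
module moves as a unit; otherwise DE genes are a random subset with
alternating signs. Defaults (2,000 genes, 30 per arm, 10% DE at
|log2FC| = 1, unit noise) mirror a small two-arm array cohort.

**Regulatory tables.** Planted feed-forward loops are sampled as distinct
(TF, miRNA) pairs with a random target mRNA and a random miRNA↔TF
direction. Placement is rejection-sampled so that planted edges never
combine into an accidental unplanted triangle — this is what makes
"recovered triples = planted triples" an exact statement at zero edge
noise; an infeasible density (too many loops for the pool) raises a
configuration error rather than silently degrading the guarantee. Decoy
edges are likewise rejection-sampled against triangle closure unless
explicitly allowed.

**PPI and genesets.** The PPI generator connects a target set (the
planted calcification core) at a configurable density with combined
scores above the medium-confidence threshold, plus low-confidence decoys
(score ≤ 0.4) among non-target genes that thresholding must discard. The
geneset generator emits one set equal to the target list plus random
background sets, GMT-serializable with stable ordering.

Every generator is a pure function of its configuration, seed included;
identical configs give bit-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: probe-level effects and annotation
mismatch, missing values, heavy-tailed or correlated noise beyond the
single-factor module structure, mean–variance coupling of microarray
intensities, hierarchically overlapping modules, and scale-free degree
structure (see the soft-threshold note below). Results on real cohorts
depend additionally on array platform, normalization, and the provenance
of the regulatory databases.

## Preprocessing

Batch adjustment is per-gene, per-batch location (optionally scale)
standardization to the pooled gene statistics. It removes additive batch
offsets exactly, is idempotent, and is deterministic; it deliberately
does not pool information across genes (no empirical-Bayes shrinkage),
which keeps the stage testable against a one-way ANOVA oracle. Scale
adjustment requires ≥ 2 samples per batch and is off by default.

Duplicate gene symbols keep the row with the highest mean expression
(ties: earliest original row) — the common array convention when probe
annotations collapse to one symbol. Z-scoring uses the sample standard
deviation (n−1) everywhere and refuses zero-variance rows by name.

The low-variance filter keeps the `ceil((1−fraction)·n)` highest-variance
genes (default fraction 0.5), with ties broken toward lexicographically
earlier symbols for determinism. The filter runs on batch-corrected,
pre-z-score values by default: after row z-scoring all variances equal 1
and a variance filter is vacuous, so the literal order "z-score, then
filter" is degenerate; both orders remain available via a flag.

Sample outliers are flagged by standardized network connectivity — row
sums of |cor| over the sample–sample correlation matrix, z-scored —
with default cut z < −2.5. This is the quantity a sample-clustering
dendrogram exposes visually; making it numeric keeps the rule
deterministic. Removing more than 20% of samples is treated as a data
problem and raises instead.

## Moderated differential expression

For gene g with pooled within-group residual variance `s_g²` on
`d = n₁ + n₂ − 2` degrees of freedom, a scaled-inverse-χ² prior
`(d₀, s₀²)` is fitted to all genes by matching the first two moments of
`log s_g²` against the log-F distribution (digamma/trigamma identities);
the trigamma inverse is solved by Newton iteration. The posterior
variance `s̃_g² = (d₀ s₀² + d s_g²)/(d₀ + d)` gives the moderated
statistic `t_g = (x̄_case − x̄_control)/(s̃_g·sqrt(1/n₁ + 1/n₂))` on
`d₀ + d` degrees of freedom, two-sided. When the observed log-variances
are underdispersed relative to the χ² expectation, `d₀ = ∞` and the
statistic reduces to a pooled-variance t with `s₀²` plugged in. A plain
Welch t is available for comparison (`method="welch"`).

Polarity is fixed as case minus control (advanced/atheroma minus
early/normal). The DEG screen is BH-adjusted p < 0.05 together with
|log2FC| > 0.1; the fold-change cut is interpreted two-sidedly since both
up- and downregulated genes are reported (a signed, up-only mode exists).
BH adjustment delegates to statsmodels' step-up implementation behind
`bh_adjust`; the test suite pins it against a literal step-up oracle.

## Weighted co-expression network

The network is unsigned, `a_ij = |cor|^β`, the conventional default when
a single power like β ≈ 10 is quoted without sign convention. The
scale-free-topology fit bins positive connectivities into 10 equal-width
bins and regresses log10(frequency) on log10(mean k per bin); the fit
index is `−sign(slope)·R²`, so an increasing (anti-scale-free) degree
trend can never satisfy the target. The smallest candidate power in
1..20 reaching R² ≥ 0.8 is selected, otherwise the best-fitting power
with a warning. Note that equal-size latent-factor modules produce an
*increasing* degree-frequency relation (many high-degree module genes,
few low-degree noise genes); a decreasing, scale-free-like law needs a
hierarchy of module sizes, which is what the test suite's cascade
fixture (module counts doubling as sizes halve) provides.

Topological overlap uses the standard unsigned formula with unit
diagonal; dissimilarity is 1 − TOM.

Module detection clusters dissTOM by average linkage and applies a
tree-variant dynamic cut with two rules: branches joining at or above an
absolute cut height (default 0.99) are always separated, and below the
cut a branch is split when its joining height exceeds the 0.9-quantile
of its internal merge heights by more than a gap of 0.1 — i.e. when the
join stands clear of the branch's internal structure. The gap rule only
fires on branches large enough to yield two modules. Clusters smaller
than `min_module_size` (default 30) are left grey/unassigned. Labels
follow the conventional size-ordered color palette and carry no
semantics; ties in size break on the smallest leaf index, so labelling
is deterministic. The hybrid PAM-stage variant of dynamic tree cut is
deliberately out of scope.

Eigengenes are the first right singular vector of the module's z-scored
gene×sample submatrix, scaled to unit variance and sign-oriented to
correlate positively with the module mean profile; variance explained is
`s₁²/Σs²`. Module merging clusters eigengenes under dissimilarity
1 − cor with average linkage, merges clusters below the merge height
(default 0.25, i.e. correlation above 0.75 — the duality c = 1 − d is
exact), recomputes eigengenes, and iterates to a fixed point; the merged
module keeps the largest member's label, and grey never merges.

The pre-WGCN noise filter drops genes whose maximum |correlation| with
any other gene is below 0.3; it is a declared correlation-based
surrogate for upstream noisy-gene screening whose exact criterion is
unspecified in common practice.

## Geneset overlap, PPI, and enrichment

Gene symbols are normalized by uppercasing and whitespace stripping only;
alias resolution against a nomenclature service is out of scope. The
calcification set is the deduplicated union of the library's sets,
optionally restricted to a curated allow-list. The CASS set is a plain
intersection with the module-retained DEGs, reported with Venn counts.

PPI edge lists use the STRING export convention (proteinA, proteinB,
combined_score; 0–1000 integer scores auto-normalized to 0–1). The
medium-confidence threshold is a strict inequality (score > 0.4).
Self-loops and duplicate/reversed rows collapse to one edge (keeping the
higher score). The induced subgraph drops queried genes with no
interaction partner inside the query, which is why PPI node counts run
below CASS counts.

Enrichment is a local one-sided Fisher exact test: p = P[X ≥ k] for
X ~ Hypergeom(N, K, n), BH-adjusted within each library. The universe
defaults to the library union and is configurable to the measured gene
set. Ranking and the p < 0.05 / top-10 filter use the raw p by default
(adjusted-p filtering is a flag); composite scores that mix z-scores
with log p are deliberately not replicated.

## Feed-forward loops

A loop is a closed triangle: miRNA→mRNA, TF→mRNA, and a miRNA↔TF edge in
either regulatory direction. The loop type records the master regulator
(miRNA-FFL, TF-FFL, or composite when both directions are reported).
The union network is undirected and unweighted — directions survive only
as annotations — and centralities are computed on it: degree; Brandes
betweenness as raw unordered-pair counts with endpoints excluded;
closeness as `(n_c − 1)/Σd` within the node's component scaled by
`(n_c − 1)/(n − 1)` (0 for isolated nodes). Both delegate to networkx
and are pinned against a Floyd–Warshall path-counting oracle in the
tests. Ranks are dense (rank 1 = most central) within each node class
and measure; the aggregate rank is their mean.

"Highest-order subnetwork motif" is formalized as: take the top
aggregate-ranked node of each class; if the triple they form was
enumerated, that is the motif; otherwise fall back to the enumerated
triple minimizing the sum of its members' aggregate ranks (ties on the
sorted triple identity). The fallback guarantees the reported motif is
always a real, enumerated FFL, and the output flags when it was used.

## Pipeline

The orchestrator is plain files plus a JSON manifest — no workflow
engine. Each stage records parameters, input checksums, and row counts;
re-running with unchanged inputs skips completed stages, and all
randomness derives from the single run seed, so identical configurations
reproduce byte-identical outputs. The bundled demo cohort uses 2,000
genes, 30 samples per arm in 2 batches, 15% DE at |log2FC| = 2 with five
40-gene modules at correlation 0.7 (DE planted inside modules, signs per
module), a 50-gene calcification core, and 30 planted FFLs over a
12×12 TF/miRNA grid. The effect size is set so that module membership —
whose latent factor inflates per-gene residual variance — does not mask
planted effects at n = 30 per arm.

## Problem sizes and limitations

Simulation-based checks use cohorts of a few hundred to a few thousand
genes and 40–60 samples: large enough for stable correlation structure
and tight Monte-Carlo error, small enough that the full suite and the
acceptance script run in minutes on one CPU. The false-discovery check
averages 200 replicates of the 2,000-gene cohort; module recovery uses
ten seeds of a 240-gene, five-module design measured by adjusted Rand
index on the non-grey partition.

Known limitations: the batch surrogate does not shrink across genes and
can overcorrect tiny batches; the tree-variant dynamic cut has two
declared tuning constants (cut height, gap) rather than the reference
implementation's deepSplit ladder; symbol normalization cannot resolve
aliases; enrichment assumes a well-defined finite universe; and the
scale-free fit is sensitive to binning on small networks. None of these
affect the exactness guarantees (TOM, BH, Fisher, centralities,
enumeration), which are pinned to closed-form or brute-force oracles.
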
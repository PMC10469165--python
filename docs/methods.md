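# Methods

This note documents the models, defaults and design choices behind
`caflineage`, and what the synthetic study conditions do and do not show.

## Single-cell preprocessing

**Filtering.** A cell is retained iff `min_genes < detected < max_genes`,
`UMI > min_umi` and mitochondrial fraction `< max_mito` (defaults 200, 6000,
1000, 0.20; all bounds exclusive on the removal side). Mitochondrial genes
are identified by a configurable prefix (default `MT-`) or an explicit list.
Filtering is idempotent; an empty result is a warning, not an error.

**Normalization.** `ln(1 + s·count/total)` per cell with `s = 10⁴`
(configurable, recorded in the output provenance). Zero counts map to zero;
values are depth-invariant within a cell.

**Variable genes.** Mean and variance are computed on the back-transformed
(expm1) normalized values; dispersion = variance/mean; the reported mean is
`log1p` of the expm1 mean; dispersions are z-standardized within 20
equal-frequency mean bins. Genes with mean strictly inside (0.0125, 3) and
standardized dispersion > 0.5 are kept, truncated to the top 1000 by
dispersion. CAF subclustering uses the exact set intersection of per-sample
variable genes (order = mean rank, ties lexicographic).

**PCA and clustering.** Per-gene z-scaling with z clipped at ±10 (guards
sparse outliers; constant genes are zeroed and logged), full-SVD PCA, and a
shared-nearest-neighbor graph (k = 20 neighbors, Jaccard edge weights,
pruned below 1/15) clustered by Leiden (RB-configuration, seeded, resolution
0.8 whole-sample / 0.6 for CAF subclustering). Resolutions are configuration:
the right value is data-dependent, and the CAF default was chosen so the
planted six-subtype structure is resolved at the default simulation geometry.
An elbow helper (max distance to the first–last chord of the scree) suggests
the PC count.

## Annotation

The classifier is a deliberate single-pass simplification of
reference-based cell typing: per cell, Spearman correlation against each
reference profile over the reference-variable genes (top quartile of
between-type variance, ties at the cutoff kept together), argmax wins;
zero-variance cells are "unassigned". Labels can instead be supplied from a
TSV — downstream logic needs only labels. The fibroblast rule is the
two-condition conjunction (classifier + ≥1 of DCN/COL3A1/THY1 with non-zero
counts, assessed on raw counts, consistent with the positive-cell
definition); tissue maps fibroblasts to CAF (tumor, border) or NF (normal).

## Cross-sample subtype matching

Cluster profiles are matrices with rows = common variable features and
columns = cells, so the CCA views share their observations (genes) and the
canonical variates are linear combinations of cells. Within- and
cross-view covariances get a ridge ε = 10⁻³ by default (cluster cell counts
can exceed the feature count, making covariances singular; ε is recorded in
the audit trail and ε = 0 raises on rank deficiency). Correlations are the
singular values of the whitened cross-covariance, clipped to [0, 1].

Pairs of clusters from different samples are ordered by ρ₁, comparing deeper
canonical correlations when two candidates differ by less than 10⁻⁹ (the tie
tolerance; the depth used is recorded). Assembly is greedy with transitive
closure: highest-correlation pair first, merges that would put two clusters
of one sample into one subtype are skipped, leftovers become singleton
subtypes. How pairwise matches should be assembled into multi-sample
subtypes is genuinely open; greedy-by-correlation is deterministic and
auditable. If one subtype clearly dominates marker expression (≥2× the next
subtype's mean), it is renamed `<marker>+`.

**DE and robust markers.** Per-gene two-sided rank-sum tests on normalized
values; genes below 10% positive cells in both groups are skipped;
avg log₂FC = log₂((mean expm1 a + ε)/(mean expm1 b + ε)) with ε = 10⁻⁹.
Small groups (combined n ≤ 20, no ties) use the exact distribution,
otherwise a tie-corrected normal approximation with continuity correction
(cross-checked against scipy per gene). Raw p enters the top-75 rule
(whether the original analysis adjusted first is unstated; BH-adjusted p is
reported alongside). Robust markers = intersection of per-sample top-75
lowest-p genes with a consistent avg log₂FC sign.

## Pseudotime and lineage genes

The trajectory method is pluggable; the quantity the analysis consumes is
the correlation ranking, which is trajectory-method-agnostic. The built-in
"principal-curve-lite": Kruskal–Wallis across the subtype+NF groups selects
ordering genes (BH-adjusted p < 0.001), cells are embedded in 2 PCs, a
polyline is threaded through the group centroids ordered by distance from
the NF centroid, and pseudotime is the arc-length of each cell's projection,
oriented so the NF mean is lowest and shifted to start at 0. Pseudotime can
also be read from a TSV (e.g. an external trajectory tool).

Per-gene Spearman ρ(expression, pseudotime) is computed per sample over the
gene intersection and averaged; zero-variance genes get ρ = 0 with a flag.
Lineage genes require CAF positive fraction ≥ 0.25, NF positive fraction
≤ 0.05 and mean ρ ≥ 0.3 (the "commonly expressed" thresholds are not
quantified in the source analysis; these defaults are configurable and
logged), ranked by ρ. The cell subset for gene–set correlations
(`marker_set_correlation`) is a required argument, since "all CAFs" vs
"marker⁺ CAFs only" is ambiguous in the source.

## Cross-talk

The scoring law is a documented simplification of mass-action models:
score = mean(expm1 ligand | senders) × mean(expm1 receptor | receivers);
p = add-one-corrected fraction of group-relabeling permutations reaching the
observed score (n_perm = 999). BH runs within each (sender, receiver)
communication family. Adjusting across the whole sample at once is
impossible in principle: a permutation p is floored at 1/(n_perm+1), so with
~2400 combination tests and a handful at the floor the smallest adjusted q
is ~0.14 — no interaction could ever be declared. The family-wise unit
matches how channel-level tools report significance, and cross-sample
intersection of interaction identities adds a second specificity filter.
Interaction frequency = count of significant interactions (incoming and
outgoing reported separately; summed weights are available alongside);
the subtype comparison is a paired Wilcoxon signed-rank with an exact
enumeration null for ≤15 pairs. With the default 3 samples the smallest
attainable one-sided p is 1/8, so the default run reports direction and
p = 0.125; the exactness contract is exercised at 6 pairs (p = 1/64).

## Enrichment

Preranked GSEA: running sum with hit increments ∝ |score|^w (w = 1 default)
normalized over the set, uniform miss decrements; ES is the extremum with
the larger magnitude, the first one reached winning magnitude ties (to
10⁻¹²). The set-equals-universe degenerate case is defined as ES = 0 and
logged. The null permutes gene labels (random same-size sets; phenotype
permutation is impossible for preranked input); NES divides ES by the mean
|ES| of same-sign permutations and the nominal p is the same-sign tail
(add-one). The ranking metric is sign(log₂FC)·(−log₁₀ p) from the rank-sum
DE (the wrapper used originally is unstated; this is the documented choice),
ties broken by gene id. Cross-sample consistency = arithmetic means of NES
and nominal p per set, with an optional name filter (e.g. names containing
MESEN or FIBRO).

## Clinical

Signature score = mean over signature genes of per-gene z-scored
log1p expression (constant genes dropped and logged; ≥50% of the signature
must be present). The score construction is not printed in the source; the
mean-z of the lineage subtype's robust markers is the package's choice, with
a single-gene mode available. CAF abundance = mean log₂(1+expression) of a
configurable marker panel. Stage bins: Stage 1/2/LOW → low,
Stage 3/4/HIGH → high.

Log-rank: O−E with hypergeometric variance summed over distinct event times.
Cox: Newton–Raphson on the Efron partial likelihood with step halving,
covariates standardized internally, convergence when the Newton step drops
below 10⁻⁸ (≤50 iterations); Wald p per covariate; separation and
non-convergence raise with diagnostics. The score (Rao) test at β = 0 equals
the log-rank statistic for a binary covariate without ties. Survival
read-out: median split by default (tertile-extremes and continuous as
alternatives, since the original dichotomization is unstated), log-rank on
the dichotomy, and Cox on both the continuous score and the dichotomy
adjusted for stage (as the binary bin), age and sex.

## Synthetic study conditions

Defaults: 3 samples × 1500 cells × 1500 genes; cell types fibroblast 40%,
epithelial/cancer 25%, endothelial 13%, T 13%, myeloid 9%; one third of
fibroblasts are NFs; 6 CAF subtypes with the lineage subtype at 30% of CAFs
(so its exclusive marker clears the 25% CAF-commonness threshold, in line
with the subtype being one of the major CAF groups); negative-binomial
counts with dispersion 0.1 on a heavy-tailed baseline; program elevation 3
log₂ units; library sizes lognormal around 6000.

The fibroblast differentiation axis is a scalar t ∈ [0, 1]: NFs occupy the
first band, each subtype a successive band, the lineage subtype the terminal
band. Two opposed gradient programs (early ∝ 1−t, late ∝ t, 60 genes each)
make the axis genuinely one-dimensional and recoverable from a 2-PC
embedding; subtype identities are 25-gene orthogonal programs. The lineage
subtype carries the marker (high-expressed, essentially dropout-free) and a
40-gene collagen program, both modulated by (1 + a·t) with a = 2; the
collagen program's expression is set so ~10% of lineage cells drop any given
collagen gene, which attenuates collagen ρ below the marker's — the
mechanism by which the marker tops the correlation ranking, mirroring an
exclusive, highly expressed terminal marker. QC violators are planted
per rule without overlap (concentrated libraries for the low-gene rule,
shallow libraries for the low-UMI rule, boosted MT weights for the
mitochondrial rule). Ligands are over-expressed in endothelial cells and
their receptors in the lineage subtype; 5× as many decoy pairs use pure
background genes.

The bulk cohort draws a latent signature s ~ N(0,1) per sample, adds it to
the log₂ expression of the signature genes, and draws exponential survival
with hazard λ₀·exp(β·s) (λ₀ = 1/1000 days) under independent exponential
censoring whose rate is calibrated by Gauss–Hermite quadrature to the
requested marginal censoring (default 0.3). Stage is "high" with probability
expit(s).

What the generator does **not** emulate: batch effects and ambient RNA,
doublets, realistic gene-count/depth distributions of specific platforms,
branching trajectories, and CAF heterogeneity beyond discrete programs on
one axis. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes when that structure is present — not that real tumors
satisfy those assumptions.

## Problem sizes and numerics

Repeated-simulation checks use 10 seeds for matching/lineage recovery, 3
full runs in the acceptance script, 50 seeds for Cox recovery at n = 500,
and 4000 replicates for the log-rank null calibration — sizes chosen so
Monte-Carlo error is small relative to the properties being checked while a
complete run stays in the minutes range. Determinism: all randomness flows
through `numpy.random.Generator` seeded from the config; fixed seeds give
bit-identical outputs on one machine. A completed run directory (containing
`summary.json`) is treated as final and not rewritten unless forced;
individual stages can be replayed via `--stages`, and recomputation is
deterministic, so replaying is equivalent to resuming.

## Known limitations

* The CCA ridge makes matching robust but slightly biases canonical
  correlations toward 0 when cell counts are small relative to features.
* The principal-curve-lite pseudotime assumes an unbranched axis whose
  group centroids are monotonically distant from the NF centroid in 2 PCs.
* The LR scorer ignores multi-subunit complexes and cofactors; scores are
  comparable within, not across, samples.
* Cox assumes proportional hazards; no diagnostics are run automatically.
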
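# caflineage

Cross-sample discovery of a lineage-terminal, marker-exclusive
cancer-associated fibroblast (CAF) subtype from multi-sample single-cell
RNA-seq, with a bulk-cohort survival read-out. The package is written for
computational biologists who want the full discovery workflow — QC,
annotation, cross-sample subtype matching, robust markers, pseudotime-based
lineage genes, ligand–receptor cross-talk, enrichment, and survival — as
tested, composable library code, exercised end to end on a bundled synthetic
generator rather than on multi-gigabyte downloads.

## The analysis

Tumor stroma contains several CAF subtypes. The workflow identifies, across
independent patient samples, one subtype that sits at the terminal end of the
fibroblast differentiation trajectory, exclusively expresses a gap-junction
marker (GJB2 in the motivating application, connexin 26) together with a
collagen program, preferentially receives endothelial signals, and whose
expression signature stratifies survival in bulk tumors. The steps:

1. **QC / normalization** — remove cells with ≤200 or ≥6000 detected genes,
   ≤1000 UMIs, or ≥20% mitochondrial counts; per-cell normalization
   `ln(1 + s·count/total)` with scale factor `s = 10⁴`.
2. **Annotation** — rank-correlation classification against reference
   profiles; a cell is a fibroblast iff the classifier agrees *and* it
   expresses ≥1 of DCN/COL3A1/THY1; tumor- and border-tissue fibroblasts are
   CAFs, normal-tissue fibroblasts NFs.
3. **Subtype matching** — CAFs are subclustered per sample (SNN graph +
   Leiden) on the intersection of per-sample variable genes. Clusters from
   different samples are compared by canonical correlation analysis of their
   feature×cell profiles; pairs are ranked by the first canonical correlation
   ρ₁ (ties broken at deeper canonical variates) and assembled greedily into
   shared subtypes.
4. **Robust markers** — per sample, rank-sum DE of each subtype vs the other
   CAFs; the 75 lowest-p genes per sample are intersected and genes with an
   inconsistent avg log₂FC sign are dropped.
5. **Lineage genes** — pseudotime over NFs + CAFs (principal-curve-lite over
   subtype-differential genes, anchored at the NF centroid); genes are ranked
   by the cross-sample mean Spearman ρ(expression, pseudotime) and filtered
   to those common in CAFs (≥25% positive) and nearly absent in NFs (≤5%).
6. **Cross-talk** — ligand–receptor score = mean(ligand|senders) ×
   mean(receptor|receivers) on back-transformed expression, permutation p by
   group relabeling; per-sample significant interactions touching CAFs are
   intersected across samples, and interaction frequencies of the lineage
   subtype are compared with the other subtypes by a paired signed-rank test.
7. **Enrichment** — preranked GSEA (weighted Kolmogorov–Smirnov running sum,
   gene-label permutation NES/p) on the marker⁺ vs marker⁻ CAF ranking,
   averaged across samples.
8. **Clinical** — bulk signature score = mean per-sample z of log1p
   expression over the robust markers; log-rank at the median split and a
   multivariate Cox model (Efron ties) adjusted for stage (binned low/high),
   age and sex.

The synthetic generator (`caflineage.simulate`) plants exactly this
structure — shared subtype programs across samples, a 1-D differentiation
axis with the marker⁺ subtype at its end, QC violators for each rule,
endothelial→lineage ligand–receptor pairs among decoys, and a bulk cohort
whose hazard is log-linear in the planted signature — so every stage is
testable offline.

## Worked example

Run the numbered drivers under `analysis/` (each replays the deterministic
pipeline through its stage and writes tables under `results/run/`):

```bash
cd analysis
python 04_match_subtypes.py   # cross-sample subtype matching
python 06_pseudotime_lineage_genes.py
python 09_bulk_survival.py
```

Matching output (seed 0): every per-sample CAF cluster joins the group of its
generating program, and the marker-dominant group is named after the marker —

```
lineage subtype: GJB2+
cluster-subtype purity vs planted programs: 100.0%
```

Lineage-gene selection: pseudotime tracks the planted axis
(|Spearman| ≈ 0.97–0.98 per sample) and the marker tops the ranking —

```
44 lineage genes selected; top 5 by mean rho:
       mean_rho   flat  caf_frac   nf_frac
GJB2   0.690887  False  0.303556  0.001701
G0166  0.674117  False  0.288027  0.001745
...
marker GJB2 rank: 1
```

`caf_frac`/`nf_frac` are positive-cell fractions (a cell is positive for a
gene if its UMI count is non-zero): the marker is expressed in ~30% of CAFs
(the planted lineage share) and ~0.2% of NFs. The survival stage reports

```
log-rank (median split): stat=157.01, p=5.1e-36
adjusted Cox (continuous score): beta=1.497, HR=4.47, p<1e-40
```

i.e. the signature carries the planted hazard after adjustment for stage,
age and sex (the coefficient is on the score scale, not the latent-signature
scale, hence >1). The same pipeline runs from the command line:
`caflineage run --seed 0 --out results/run`.

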
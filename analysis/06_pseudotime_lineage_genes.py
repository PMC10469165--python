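"""Order fibroblasts in pseudotime and select lineage-specific genes.

Pseudotime comes from a principal-curve-lite fit on subtype-differential
genes; lineage genes must be common in CAFs (>=25%% positive), nearly absent
from NFs (<=5%%) and rise with pseudotime (mean Spearman rho >= 0.3).
"""

from scipy.stats import spearmanr

from _common import run_through

state = run_through("lineage_genes", __doc__)
for sample in state.samples:
    pt = state.pseudotime[sample]
    true_t = state.truth.cells.loc[pt.index, "pseudotime"]
    rho = abs(spearmanr(pt, true_t).statistic)
    print(f"{sample}: |Spearman|(inferred, planted pseudotime) = {rho:.3f}")
sel = state.lineage_genes
print(f"\n{len(sel)} lineage genes selected; top 5 by mean rho:")
print(sel.head(5).to_string())
marker = state.truth.marker_gene
rank = list(sel.index).index(marker) + 1 if marker in sel.index else None
print(f"marker {marker} rank: {rank}")
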
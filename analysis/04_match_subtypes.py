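"""Subcluster CAFs per sample and match clusters across samples by CCA.

Per-sample clusters on common variable features are paired by the highest
first canonical correlation (deeper canonical variates break ties) and
assembled greedily into shared subtypes; the marker-dominant subtype is
named after the marker gene.
"""

from _common import run_through

state = run_through("match", __doc__)
print(state.correspondence.assignment.to_string(index=False))
print(f"\nlineage subtype: {state.lineage_subtype}")
caf = state.cell_table[state.cell_table["fib_class"] == "CAF"]
truth = state.truth.cells.loc[caf.index, "subtype"]
import pandas as pd

tab = pd.crosstab(caf["subtype"], truth)
purity = tab.max(axis=1).sum() / tab.to_numpy().sum()
print(f"cluster-subtype purity vs planted programs: {purity:.1%}")
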
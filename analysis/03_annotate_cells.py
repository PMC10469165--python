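"""Type cells against the reference and apply the fibroblast/CAF rule.

A cell is a fibroblast iff the rank-correlation classifier says so AND it
expresses at least one of DCN/COL3A1/THY1; tumor- and border-tissue
fibroblasts become CAFs, normal-tissue fibroblasts NFs.
"""

from _common import run_through

state = run_through("annotate", __doc__)
ct = state.cell_table
print(ct["fib_class"].value_counts().to_string())
truth = state.truth.cells.loc[ct.index]
acc = (ct["classifier_label"] == truth["cell_type"]).mean()
print(f"classifier accuracy vs planted types: {acc:.1%}")
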
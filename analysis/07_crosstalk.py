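"""Score ligand-receptor cross-talk per sample and intersect across samples.

Interaction score = product of sender-mean ligand and receiver-mean receptor
expression with a group-relabeling permutation p; significant interactions
touching CAFs are intersected across samples, and incoming interaction
frequencies of the lineage subtype are compared with the other CAF subtypes.
"""

from _common import run_through

state = run_through("crosstalk", __doc__)
print(f"interactions involving CAFs common to all samples:")
for ident in sorted(state.common_lr):
    print("  ", ident)
print(f"\npaired comparison (lineage vs other CAF subtypes, incoming): "
      f"{state.frequency_test}")
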
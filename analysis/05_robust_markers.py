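"""Find robust subtype markers: top-75 lowest-p DE genes intersected across
samples, keeping only genes with a consistent log2 fold-change sign."""

from _common import run_through

state = run_through("markers", __doc__)
for st, tab in state.marker_tables.items():
    print(f"{st}: {len(tab)} robust markers; top 5: {list(tab.index[:5])}")
lm = state.lineage_markers
program = set(state.truth.programs["lineage"])
rec = len(set(lm.index) & program) / len(program)
print(f"\nlineage subtype: marker gene present = "
      f"{state.truth.marker_gene in lm.index}; "
      f"collagen-program recovery = {rec:.0%}")
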
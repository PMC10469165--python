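"""Preranked gene-set enrichment of marker-positive vs marker-negative CAFs,
averaged across samples (NES and nominal p)."""

from _common import run_through

state = run_through("gsea", __doc__)
print(state.enrichment_table.to_string())

print("\nwith the mesenchymal/fibroblast name filter:")
flt = state.enrichment_table[
    state.enrichment_table.index.str.contains("MESEN|FIBRO")
]
print(flt.to_string())
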
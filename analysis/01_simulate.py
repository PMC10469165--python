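"""Generate the synthetic multi-sample discovery dataset.

Writes per-sample 10x triplets, the cell metadata, reference profiles, the
ligand-receptor table, gene sets and the planted ground truth under
results/run, and summarizes what was planted.
"""

from _common import run_through

state = run_through("simulate", __doc__)
cfg = state.config.synthetic
truth = state.truth
print(f"samples: {len(state.adatas)} x {cfg.cells_per_sample} cells, "
      f"{cfg.n_genes} genes")
print(f"CAF subtypes: {cfg.n_caf_subtypes}; lineage subtype = "
      f"{truth.lineage_subtype} ({cfg.lineage_caf_fraction:.0%} of CAFs), "
      f"marker = {truth.marker_gene}")
print(f"collagen program: {len(truth.programs['lineage'])} genes; "
      f"planted LR pairs: {[(l, r) for l, r, _, _ in truth.lr_planted]}")
viol = truth.cells["qc_violation"].value_counts().to_dict()
print(f"planted QC violations per rule: "
      f"{ {k: v for k, v in viol.items() if k != 'none'} }")
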
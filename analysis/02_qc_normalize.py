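"""Filter low-quality cells and log-normalize each sample.

Cells with <=200 or >=6000 detected genes, <=1000 UMIs or >=20%%
mitochondrial reads are removed; the QC report lands in results/run.
"""

from _common import run_through

state = run_through("qc", __doc__)
for a in state.adatas:
    print(f"{a.obs['sample'].iloc[0]}: {a.n_obs} cells retained after QC")
truth = state.truth.cells
kept = truth.loc[[b for a in state.adatas for b in a.obs_names]]
print(f"all retained cells are violation-free: "
      f"{(kept['qc_violation'] == 'none').all()}")
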
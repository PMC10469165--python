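import numpy as np
import pytest

from caflineage import pipeline
from caflineage.config import PipelineConfig, SyntheticConfig


def make_config(seed: int = 0, **synthetic_overrides) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed)
    cfg.synthetic.seed = seed
    for k, v in synthetic_overrides.items():
        setattr(cfg.synthetic, k, v)
    return cfg


@pytest.fixture(scope="session")
def run_state(tmp_path_factory):
    """One full default pipeline run (all stages, seed 0)."""
    return pipeline.run_pipeline(
        make_config(0), tmp_path_factory.mktemp("full_run"), force=True
    )


@pytest.fixture(scope="session")
def multiseed_states(tmp_path_factory):
    """Ten seeded runs through subtype matching and lineage-gene selection,
    shared by the recovery statistics that need repeated simulations."""
    stages = (
        "simulate", "qc", "annotate", "subcluster", "match",
        "pseudotime", "lineage_genes",
    )
    states = []
    for seed in range(10):
        cfg = make_config(seed)
        state = pipeline.RunState(
            config=cfg, outdir=tmp_path_factory.mktemp(f"seed{seed}")
        )
        for name in stages:
            pipeline._STAGE_FUNCS[name](state)
        states.append(state)
    return states


@pytest.fixture(scope="session")
def qc_fixture_100():
    """100 synthetic cells with exactly 10 planted, non-overlapping QC
    violations (4 low-gene, 3 low-UMI, 3 high-mito)."""
    cfg = SyntheticConfig(
        n_samples=1,
        cells_per_sample=100,
        qc_violation_fractions={"low_genes": 0.04, "low_umi": 0.03, "high_mito": 0.03},
        seed=7,
    )
    from caflineage.simulate import generate_multisample_sc

    adatas, truth = generate_multisample_sc(cfg)
    return adatas[0], truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
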
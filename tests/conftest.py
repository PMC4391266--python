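import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from guildphylo import PipelineConfig, all_vs_all
from guildphylo.pipeline import simulate_stage


def small_config(seed: int = 5) -> PipelineConfig:
    """A fast desk-scale configuration for unit-level pipeline checks."""
    cfg = PipelineConfig(seed=seed, outdir="scratch/test_run")
    cfg.simulate.n_taxa = 8
    cfg.simulate.n_core = 6
    cfg.simulate.n_accessory = 6
    cfg.simulate.n_biased = 6
    cfg.simulate.root_len = 60
    cfg.tree.bootstrap_reps = 20
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated proteomes + truth + all-vs-all hits, shared across tests."""
    cfg = small_config()
    proteomes, truth = simulate_stage(cfg)
    hits = all_vs_all(proteomes)
    return cfg, proteomes, truth, hits
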
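import numpy as np
import pandas as pd
import pytest

from synet import ExpressionCompendium, SynthConfig, simulate_compendium


@pytest.fixture
def tiny_compendium() -> ExpressionCompendium:
    """3 studies x 4 samples x 3 genes, fully labelled, handmade."""
    rng = np.random.default_rng(42)
    samples = [f"S{k}" for k in range(12)]
    values = pd.DataFrame(rng.normal(size=(12, 3)),
                          index=samples, columns=["GA", "GB", "GC"])
    annot = pd.DataFrame({
        "study": ["ST1"] * 4 + ["ST2"] * 4 + ["ST3"] * 4,
        "survival_time": [2.0, 8.0, 1.0, 6.0] * 3,
        "event": [1, 0, 1, 1] * 3,
    }, index=samples)
    return ExpressionCompendium(values, annot)


@pytest.fixture(scope="session")
def small_synth():
    """Small planted compendium reused across tests: 3 studies x 80,
    40 genes, 4 marginal genes, 3 synergy pairs, 2 blocks."""
    cfg = SynthConfig(n_studies=3, samples_per_study=80, n_genes=40,
                      n_marginal=4, n_synergy_pairs=3, n_corr_blocks=2,
                      block_size=5, seed=7)
    return simulate_compendium(cfg)
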
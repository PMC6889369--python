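import numpy as np
import pandas as pd
import pytest

from mircade.config import AnalysisConfig, SimulationConfig
from mircade.simulate import plant_truth, synthesize_sequences


def small_sim_config(**overrides) -> SimulationConfig:
    """A desk-scale simulation: 120 genes, 8 cascades, 3 enriched miRNAs."""
    base = dict(
        n_genes=120,
        n_mirnas=8,
        n_enriched=3,
        n_tfs=4,
        n_cascades=8,
        n_direct_extra=5,
        n_decoy_peaks=60,
        genome_length=4_000_000,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def truth(sim_config):
    return plant_truth(sim_config)


@pytest.fixture(scope="session")
def sequences(sim_config, truth):
    return synthesize_sequences(truth, sim_config)


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig(n_permutations=2000, seed=5)


def random_expression(n_genes: int, n_case: int, n_ctrl: int, seed: int,
                      shifts: dict[int, float] | None = None,
                      sd_log2: float = 0.15):
    """Log-normal expression around a common baseline with optional planted
    log2 shifts on case samples (index -> shift)."""
    from mircade.screen import ExpressionMatrix

    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(20.0), 1.0, size=n_genes)
    shift = np.zeros(n_genes)
    for i, s in (shifts or {}).items():
        shift[i] = s
    case = base[:, None] * 2.0 ** (
        shift[:, None] + rng.normal(0, sd_log2, (n_genes, n_case))
    )
    ctrl = base[:, None] * 2.0 ** rng.normal(0, sd_log2, (n_genes, n_ctrl))
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"case_{j}" for j in range(n_case)] + [f"ctrl_{j}" for j in range(n_ctrl)]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=cols)
    labels = {c: ("case" if c.startswith("case") else "control") for c in cols}
    return ExpressionMatrix(values, labels)
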
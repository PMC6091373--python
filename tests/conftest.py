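import numpy as np
import pandas as pd
import pytest

from fpathseq.data import ExpressionStudy, GeneSetCollection
from fpathseq.synthetic import SimulationConfig, simulate_study


def make_study(values, groups=None, sources=None, times=None, genes=None):
    """Assemble a small ExpressionStudy from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame({
        "group": groups or ["patient"] * n_samples,
        "source": sources or ["blood"] * n_samples,
        "time_h": times or [0] * n_samples,
    }, index=pd.Index(sample_ids, name="sample_id"))
    mat = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return ExpressionStudy(mat, meta)


@pytest.fixture
def small_config():
    """A quick-to-simulate single-source planted design."""
    return SimulationConfig(
        n_genes=300, n_pathways=8, pathway_size_range=(10, 16),
        overlap_fraction=0.1, n_controls=3, n_patients=8,
        sources=("blood",), n_active_pathways=2,
        effect_size=2.0, noise_sd=0.5, q=0.1, seed=7,
    )


@pytest.fixture
def small_simulation(small_config):
    return simulate_study(small_config)


@pytest.fixture
def toy_collection():
    return GeneSetCollection({
        "setA": frozenset({"g0", "g1", "g2"}),
        "setB": frozenset({"g2", "g3", "g4", "g5"}),
    })
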
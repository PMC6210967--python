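import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from panevo import EvolutionModel, PanGenomeModel, generate_pangenome


@pytest.fixture(scope="session")
def small_dataset():
    """Six genomes, closed pool: small enough for unit tests, rich enough
    to exercise core/accessory/unique structure."""
    model = PanGenomeModel(
        n_genomes=6, core_families=25, openness_mode="closed", pool_size=45,
        mean_length_codons=90, min_length_codons=40, seed=42,
    )
    evo = EvolutionModel(omega_target=0.2, ks_target=0.4, seed=42)
    return generate_pangenome(model, evo)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def random_codon_matrix(rng, n_families, n_genomes, density=0.5):
    """Random 0/1 presence matrix as a pandas DataFrame."""
    import pandas as pd

    mat = (rng.random((n_families, n_genomes)) < density).astype(int)
    return pd.DataFrame(
        mat,
        index=[f"F{i:04d}" for i in range(n_families)],
        columns=[f"G{j:03d}" for j in range(n_genomes)],
    )
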
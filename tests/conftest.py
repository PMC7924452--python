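import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from fairpredict import GeneratorConfig, generate_knowledge_base, build_similarity_matrices


@pytest.fixture(scope="session")
def small_kb():
    """30-drug clustered KB at the default signal/noise levels."""
    cfg = GeneratorConfig(
        n_drugs=30, n_diseases=20, n_proteins=30, n_clusters=5, seed=11
    )
    return generate_knowledge_base(cfg)


@pytest.fixture(scope="session")
def small_matrices(small_kb):
    return build_similarity_matrices(small_kb)


@pytest.fixture(scope="session")
def clean_kb():
    """Noise-free, fully on-cluster KB for separation properties."""
    cfg = GeneratorConfig(
        n_drugs=40, n_diseases=20, n_proteins=30, n_clusters=5,
        signal_strength=1.0, modality_noise=0.0, seed=5,
    )
    return generate_knowledge_base(cfg)
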
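import numpy as np
import pytest

from creanet import synthetic as syn


@pytest.fixture(scope="session")
def two_cluster_lexicon():
    """Two orthogonal clusters, mild within-cluster noise."""
    return syn.make_lexicon(
        syn.LexiconSpec(n_clusters=2, words_per_cluster=5, dim=8, within_noise_sd=0.05, seed=1)
    )


@pytest.fixture(scope="session")
def clean_two_cluster_lexicon():
    """Two orthogonal clusters, zero noise: within-cluster vectors identical."""
    return syn.make_lexicon(
        syn.LexiconSpec(n_clusters=2, words_per_cluster=3, dim=8, within_noise_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def planted_bold_spec():
    """Block-structured BOLD: 3 blocks over 30 nodes, T=10x30=300 concatenated."""
    return syn.BoldSpec(
        n_nodes=30,
        n_networks=6,
        n_blocks=3,
        T_trial=30,
        n_trials=10,
        n_subjects=3,
        noise_sd=0.1,
        seed=5,
    )


@pytest.fixture(scope="session")
def planted_bold(planted_bold_spec):
    return syn.make_bold(planted_bold_spec)
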
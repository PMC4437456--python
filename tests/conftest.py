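import importlib.resources

import numpy as np
import pytest

import panphen as pp


@pytest.fixture(scope="session")
def api50ch_table() -> pp.PhenotypeTable:
    """The transcribed 21-strain API 50CH sugar score table."""
    path = importlib.resources.files("panphen") / "data" / "pf21_api50ch.tsv"
    return pp.read_phenotype_table(str(path))


@pytest.fixture(scope="session")
def small_panel() -> pp.SimPanel:
    """A modest synthetic panel shared by read-only tests."""
    cfg = pp.SimConfig(n_strains=10, n_core=5, n_decoy_accessory=30,
                       island_size=3, seed=11)
    return pp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def sequence_panel() -> pp.SimPanel:
    """A small panel with emitted sequences and planted nonsense mutations."""
    cfg = pp.SimConfig(n_strains=8, n_core=4, n_decoy_accessory=12,
                       island_size=3, nonsense_fraction=0.5,
                       cds_codons=(100, 200), seed=23)
    return pp.simulate_panel(cfg, with_sequences=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(4242)
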
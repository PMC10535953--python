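import numpy as np
import pytest

from mcqsar.dataset import Compound, Dataset, split_dataset
from mcqsar.synthetic import GeneratorConfig, generate_dataset, generate_smiles


@pytest.fixture(scope="session")
def smiles_corpus() -> list[str]:
    """A mixed corpus: hand-picked structures plus generator output."""
    fixed = [
        "CCO",
        "c1ccccc1",
        "Clc1ccccc1",
        "CC(C)C",
        "CC(=O)Oc1ccccc1",
        "C%11CCCC%11",
        "N#Cc1ccncc1",
        "OC(=O)C(N)Cc1ccccc1",
        "FC(F)(F)c1ccccc1",
        "C1CCNCC1",
        "BrCCBr",
        "C/C=C/C",
        "[NH4+]",
        "CC[N+](C)(C)CC",
    ]
    rng = np.random.default_rng(2024)
    cfg = GeneratorConfig(seed=0)
    return fixed + [generate_smiles(rng, cfg) for _ in range(40)]


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """A 60-compound labelled synthetic dataset (noise-free)."""
    cfg = GeneratorConfig(n_compounds=60, seed=123, noise_sd=0.0)
    ds = generate_dataset(cfg).dataset
    ds.apply_split(split_dataset([c.compound_id for c in ds], seed=7))
    return ds


@pytest.fixture()
def toy_dataset() -> Dataset:
    """Eight hand-written compounds, one per subset pair."""
    rows = [
        ("c1", "CCO", 1.0, "active"),
        ("c2", "CCC", 2.0, "active"),
        ("c3", "CCN", 1.5, "passive"),
        ("c4", "CC(C)C", 2.5, "passive"),
        ("c5", "c1ccccc1", 3.0, "calibration"),
        ("c6", "CCCC", 2.2, "calibration"),
        ("c7", "CCOC", 1.8, "validation"),
        ("c8", "CCCO", 1.2, "validation"),
    ]
    return Dataset([Compound(*r) for r in rows])
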
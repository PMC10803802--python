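import pandas as pd
import pytest

from drgkit import DrgCatalog, GeneratorConfig, dissect, generate_catalog, generate_corpus

TOY_ROWS = [
    (1, "ALPHA CONDITION WITH MCC"),
    (2, "ALPHA CONDITION WITH CC"),
    (3, "ALPHA CONDITION WITHOUT CC/MCC"),
    (4, "BETA PROCEDURE WITH CC/MCC"),
    (5, "BETA PROCEDURE WITHOUT CC/MCC"),
    (6, "GAMMA REPAIR WITH MCC"),
    (7, "GAMMA REPAIR WITHOUT MCC"),
    (8, "TRANSIENT ISCHEMIA"),
]


@pytest.fixture(scope="session")
def toy_catalog() -> DrgCatalog:
    """One family of each split type: three-way, both two-ways, unsplit."""
    return DrgCatalog.from_rows(TOY_ROWS)


@pytest.fixture(scope="session")
def toy_space(toy_catalog):
    return dissect(toy_catalog)


@pytest.fixture(scope="session")
def small_corpus():
    """A generated catalog + corpus shared by corpus/model tests."""
    cfg = GeneratorConfig(n_base_families=8, n_records=400, seed=11)
    catalog = generate_catalog(cfg)
    corpus, truth = generate_corpus(catalog, cfg)
    return catalog, corpus, truth, cfg
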
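import datetime as dt

import pytest

from iiinet.data_io import Isoform, IsoformCatalog, PPIRecord
from iiinet.synthetic_data import SyntheticWorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """One shared synthetic world with planted signal (expensive to build)."""
    return generate_world(SyntheticWorldConfig(seed=11))


@pytest.fixture(scope="session")
def small_world():
    """A quick-to-generate world for smoke and determinism checks."""
    cfg = SyntheticWorldConfig(
        seed=5,
        n_genes=40,
        n_ppis=60,
        n_datasets=3,
        samples_per_dataset=12,
        n_planted_modules=2,
        planted_module_size=4,
        n_background_terms=10,
    )
    return generate_world(cfg)


@pytest.fixture
def tiny_catalog():
    return IsoformCatalog(
        [
            Isoform("NM_000001", "GENE1", frozenset({"PF00001"})),
            Isoform("NM_000002", "GENE1", frozenset({"PF00002"})),
            Isoform("NM_000003", "GENE2", frozenset({"PF00003"})),
            Isoform("NM_000004", "GENE3", frozenset()),
            Isoform("NM_000005", "GENE4", frozenset({"PF00001", "PF00004"})),
        ]
    )


@pytest.fixture
def ppi_records():
    return [
        PPIRecord("GENE1", "GENE2", None, None, dt.date(2011, 5, 1)),
        PPIRecord("GENE2", "GENE3", None, None, dt.date(2012, 6, 1)),
        PPIRecord(
            "GENE1", "GENE2", "NM_000001", "NM_000003", dt.date(2012, 6, 1)
        ),
    ]
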
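import numpy as np
import pytest

from replix.catalog import CatalogEntry


@pytest.fixture
def rng():
    return np.random.default_rng(20211)


def make_entry(**over):
    """A valid binary catalog entry with overridable fields."""
    base = dict(
        snp_id="rs1",
        phenotype="disease_x",
        risk_allele="A",
        other_allele="G",
        raf_controls=0.2,
        effect=1.3,
        trait_type="binary",
        p_value=1e-9,
        ancestry="European",
        study_id="PMID1",
        n_cases=2000,
        n_controls=3000,
    )
    base.update(over)
    return CatalogEntry(**base)


@pytest.fixture
def entry_factory():
    return make_entry
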
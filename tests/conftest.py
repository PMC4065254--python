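import pandas as pd
import pytest

import minmod as mm
from minmod import datasets


@pytest.fixture(scope="session")
def colony() -> mm.ColonyModel:
    return mm.ColonyModel()


@pytest.fixture(scope="session")
def baseline(colony) -> mm.NegativeBinomialPhenotype:
    return colony.phenotype_model()


@pytest.fixture(scope="session")
def default_mixture() -> mm.MixtureParams:
    return mm.MixtureParams(
        weights=datasets.MODIFIER_CLASS_WEIGHTS,
        suppressor=mm.TruncatedLogNormalEffect.suppressor(),
        enhancer=mm.TruncatedLogNormalEffect.enhancer(),
    )


@pytest.fixture(scope="session")
def published_table() -> mm.LineVariantTable:
    """Synthetic variant table realising the published per-chromosome counts."""
    return mm.variant_table_from_published_counts(seed=0)


@pytest.fixture(scope="session")
def published_partition(published_table):
    return mm.partition_line_specific(published_table, related_pair=datasets.RELATED_PAIR)


@pytest.fixture(scope="session")
def line_specific_records(published_partition) -> pd.DataFrame:
    return pd.concat(list(published_partition.exclusive.values()), ignore_index=True)
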
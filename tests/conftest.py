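import pandas as pd
import pytest

from pfn.converters import FeatureTable
from pfn.fixtures import FixtureSpec, gen_records


@pytest.fixture(scope="session")
def p25_feature_table() -> FeatureTable:
    """Synthetic feature table carrying the p25 chain row (the residue
    range that UniProtKB assigns to feature PRO_0000004795 of Q15078)."""
    return FeatureTable(
        pd.DataFrame(
            [
                ("Q15078", "PRO_0000004795", 99, 307),
                ("Q15078", "PRO_0000004794", 1, 98),
                ("P04637", "PRO_0000185703", 2, 393),
            ],
            columns=["accession", "feature_id", "start", "end"],
        )
    )


@pytest.fixture(scope="session")
def record_batch():
    """1000 seeded random records with brute-force canonical strings."""
    return gen_records(FixtureSpec(seed=7, n_records=1000))


@pytest.fixture(scope="session")
def small_batch():
    return gen_records(FixtureSpec(seed=11, n_records=300))
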
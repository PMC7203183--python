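import pandas as pd
import pytest

from minirings import load_fixture_tables


@pytest.fixture(scope="session")
def tables():
    return load_fixture_tables()


@pytest.fixture(scope="session")
def ring25_features(tables) -> pd.DataFrame:
    """The reference ring's 22-splicing feature table with a ring_id column."""
    df = tables.ring25.copy()
    df.insert(0, "ring_id", 25)
    return df


@pytest.fixture(scope="session")
def thermus_rh(ring25_features, tables):
    """rH values of the reference ring against Thermus, default convention."""
    from minirings import rh_table

    rh = rh_table(ring25_features, tables.subelements, z_mode="identity")
    return rh[rh["organism"] == "Thermus thermophilus"]
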
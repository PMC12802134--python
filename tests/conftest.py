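import numpy as np
import pandas as pd
import pytest

from mmrules.containers import FeatureTable, SubjectLabels
from mmrules.simulate import fabricate_baseline


@pytest.fixture(scope="session")
def baseline():
    """One fabricated baseline cohort shared across tests (seeded)."""
    return fabricate_baseline(seed=1)


@pytest.fixture(scope="session")
def small_baseline():
    """A small cohort for fast end-to-end plumbing tests."""
    return fabricate_baseline(n_subjects=40, n_taxa=40, n_metab=30, seed=3)


@pytest.fixture
def tiny_taxa_table():
    df = pd.DataFrame(
        [[12, 0, 3], [8, 15, 3], [30, 2, 3]],
        index=["s1", "s2", "s3"],
        columns=["tA", "tB", "tC"],
    )
    return FeatureTable(df, "taxa", "raw")


@pytest.fixture
def tiny_metab_table():
    df = pd.DataFrame(
        [[1.0, 5.0], [3.0, 0.0], [9.0, 2.0]],
        index=["s1", "s2", "s3"],
        columns=["mA", "mB"],
    )
    return FeatureTable(df, "metabolite", "raw")


@pytest.fixture
def tiny_labels():
    return SubjectLabels(
        pd.Series([0, 1, 1], index=pd.Index(["s1", "s2", "s3"], name="subject_id"))
    )
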
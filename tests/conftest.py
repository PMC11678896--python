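import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hemnet.datamodel import ExpressionCohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """3 genes x 4 subjects, two diseases, first gene a TF."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 9.0, 1.0, 7.0], [2.0, 2.0, 2.0, 8.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series(["A", "A", "B", "B"], index=values.columns, name="disease")
    return ExpressionCohort(values=values, disease_of=labels, tf_ids=["g1"])


@pytest.fixture
def toy_network_inputs(rng):
    """3 TF x 5 gene toy PANDA instance."""
    tfs = [f"t{i}" for i in range(3)]
    genes = [f"g{i}" for i in range(5)]
    motif = pd.DataFrame(
        (rng.random((3, 5)) < 0.4).astype(float), index=tfs, columns=genes
    )
    motif.iloc[0, 0] = 1.0  # keep prior non-constant
    ppi = np.triu((rng.random((3, 3)) < 0.5).astype(float), 1)
    ppi = ppi + ppi.T
    np.fill_diagonal(ppi, 1.0)
    ppi = pd.DataFrame(ppi, index=tfs, columns=tfs)
    x = rng.normal(0, 1, (5, 12))
    coexpr = pd.DataFrame(np.corrcoef(x), index=genes, columns=genes)
    return motif, ppi, coexpr
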
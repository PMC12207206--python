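import numpy as np
import pandas as pd
import pytest

from rwe_ici import expression, synth


@pytest.fixture(scope="session")
def cohort300():
    """Shared full synthetic cohort: 300 patients, 2,000 genes, seed 7."""
    return synth.generate_all(synth.SynthConfig(n_patients=300, n_genes=2000, seed=7))


@pytest.fixture(scope="session")
def norm300(cohort300):
    return expression.normalize_counts(cohort300.counts)


@pytest.fixture()
def nb_counts():
    """Small 4-sample negative-binomial count fixture with unequal depths."""
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4.0, 1.5, 400)
    cols = {}
    for j, depth in enumerate([1.0, 2.2, 0.6, 1.4]):
        m = mu * depth
        cols[f"s{j}"] = rng.negative_binomial(8, 8 / (8 + m))
    df = pd.DataFrame(cols, index=[f"g{i:03d}" for i in range(400)])
    return df
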
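import numpy as np
import pandas as pd
import pytest

from stadsub.io import OmicsLayer
from stadsub.synthetic import CohortConfig, generate_cohort


def make_layer(values, kind="EXP", features=None, samples=None, centered=True):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsLayer(kind, pd.DataFrame(values, index=features, columns=samples), centered=centered)


def correlated_rows(x, targets, rng):
    """Rows with exact sample Pearson correlation `targets` against x."""
    n = len(x)
    xs = (x - x.mean()) / x.std()
    cols = [np.ones(n), xs] + [rng.normal(size=n) for _ in targets]
    basis = np.linalg.qr(np.column_stack(cols))[0]
    rows = []
    for i, r in enumerate(targets):
        z = basis[:, i + 2]  # zero mean, orthogonal to xs
        rows.append(r * xs + np.sqrt(1 - r**2) * z / z.std())
    return np.array(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by unit tests (not acceptance checks)."""
    return generate_cohort(CohortConfig(seed=101, n_samples=120, n_genes=400))
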
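import numpy as np
import pandas as pd
import pytest

from cisfine.genotype_io import GenotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_panel(dosages, chrom="1", start_pos=100, spacing=50):
    """Panel with programmatic metadata around a given dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(p)],
            "chrom": str(chrom),
            "pos": start_pos + spacing * np.arange(p),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypePanel(dosages, [f"s{i}" for i in range(n)], variants)


@pytest.fixture
def small_panel():
    return make_panel([[0, 2], [1, 0], [2, 1]])


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the solver kernels once so per-test timings stay meaningful."""
    from cisfine import PenaltySpec, fit_l0l1

    rng = np.random.default_rng(123)
    X = rng.standard_normal((20, 4))
    y = X[:, 0] + rng.standard_normal(20)
    fit_l0l1(X, y, PenaltySpec(0.1, 0.1))
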
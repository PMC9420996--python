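import numpy as np
import pytest

from stratccd import ClockGenePanel, ExpressionMatrix, default_reference


@pytest.fixture(scope="session")
def reference():
    """The shipped synthetic entrained-cohort reference (cached)."""
    return default_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_expression(rng, n_genes=5, n_samples=10, prefix="G"):
    genes = [f"{prefix}{i}" for i in range(n_genes)]
    samples = [f"S{i}" for i in range(n_samples)]
    return ExpressionMatrix(genes, samples, rng.normal(size=(n_genes, n_samples)))


def random_correlation_values(rng, n):
    """A valid correlation-like symmetric matrix with unit diagonal."""
    x = rng.normal(size=(n, n + 3))
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2, -1, 1)
    np.fill_diagonal(c, 1.0)
    return c


@pytest.fixture()
def small_panel():
    return ClockGenePanel(("G0", "G1", "G2", "G3"), min_genes=3)
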
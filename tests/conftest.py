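import numpy as np
import pytest

from moplsda import ExpressionMatrix, SyntheticSpec, generate


def make_matrix(values, state="raw", labels=None, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    gene_ids = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    sample_ids = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    if labels is not None:
        labels = {s: c for s, c in zip(sample_ids, labels)}
    return ExpressionMatrix(values=values, gene_ids=gene_ids,
                            sample_ids=sample_ids, labels=labels, state=state)


def centered_random(rng, n_samples, n_genes):
    """Column-centered random matrix for model-fitting tests."""
    X = rng.normal(size=(n_samples, n_genes))
    return X - X.mean(axis=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at generator defaults (parallel contrasts)."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick small dataset for pipeline-level tests."""
    spec = SyntheticSpec(n_genes=400, n_markers_per_contrast=(10, 10), seed=3)
    return spec, generate(spec)
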
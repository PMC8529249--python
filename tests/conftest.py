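import numpy as np
import pytest

from phylonb.io import CountMatrix, CovariateVector, FamilyMap


@pytest.fixture
def toy_counts():
    return CountMatrix(
        subject_ids=["s1", "s2", "s3"],
        otu_ids=["otuA", "otuB"],
        counts=np.array([[1, 2], [3, 4], [0, 5]]),
    )


@pytest.fixture
def tiny_dataset():
    """Small two-family dataset with reproducible Poisson-ish counts."""
    rng = np.random.default_rng(7)
    n, j = 40, 6
    fam = np.array([0, 0, 0, 1, 1, 1])
    x = rng.normal(0, 1, n)
    alpha = rng.normal(2.0, 0.1, j)
    beta = np.where(fam == 0, 0.0, 0.8) + rng.normal(0, 0.1, j)
    mu = np.exp(alpha + np.outer(x, beta))
    counts = rng.poisson(mu)
    subject_ids = [f"s{i}" for i in range(n)]
    otu_ids = [f"o{k}" for k in range(j)]
    cm = CountMatrix(subject_ids, otu_ids, counts, totals=np.ones(n, dtype=int))
    fmap = FamilyMap({o: f"fam{f}" for o, f in zip(otu_ids, fam)})
    cov = CovariateVector(subject_ids, x, name="food")
    return cm, fmap, cov, {"alpha": alpha, "beta": beta, "fam": fam, "x": x}
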
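import numpy as np
import pandas as pd
import pytest

from syndromekit import synthetic_data


@pytest.fixture(scope="session")
def study_fixture():
    """Deterministic study-shaped drift-only bundle (13 pops, 17 loci)."""
    return synthetic_data.make_study_fixture(seed=1)


@pytest.fixture(scope="session")
def balanced_cov13():
    """Brownian covariance matrix of a balanced 13-tip ultrametric tree:
    six cherries splitting at depth 0.85, quartets at 0.5, a backbone at 0.2,
    plus one tip from the root.  Deep nested structure makes Pagel's lambda
    well identified at 13 tips."""
    G = 13
    C = np.zeros((G, G))
    for i in range(G):
        for j in range(G):
            if i == j:
                C[i, j] = 1.0
            elif i < 12 and j < 12 and i // 2 == j // 2:
                C[i, j] = 0.85
            elif i < 12 and j < 12 and i // 4 == j // 4:
                C[i, j] = 0.5
            elif i < 12 and j < 12:
                C[i, j] = 0.2
    return C


@pytest.fixture
def toy_genotypes():
    """2 populations x 10 individuals x 2 loci, seeded draws."""
    rng = np.random.default_rng(5)
    rows = []
    freqs = {"A": [0.8, 0.2], "B": [0.3, 0.7]}
    for pop in ("A", "B"):
        for i in range(10):
            for locus in ("L1", "L2"):
                a, b = rng.choice([1, 2], size=2, p=freqs[pop])
                rows.append((f"{pop}{i}", pop, locus, a, b))
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "population_id", "locus_id",
                 "allele_a", "allele_b"],
    )
    df["allele_a"] = df["allele_a"].astype("Int64")
    df["allele_b"] = df["allele_b"].astype("Int64")
    return df
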
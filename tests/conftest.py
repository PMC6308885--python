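import numpy as np
import pandas as pd
import pytest

from sgdc import GenotypeMatrix, CommunityTable, EnvironmentTable, load_carex_sites


@pytest.fixture(scope="session")
def carex_table() -> pd.DataFrame:
    """Packaged per-site reference table for the Andean wetland system."""
    return load_carex_sites()


@pytest.fixture
def make_gm():
    """Build a GenotypeMatrix from a dosage array with sensible defaults."""

    def build(dosage, populations=None, depth=None, **kw):
        dosage = np.asarray(dosage, dtype=np.int8)
        n, L = dosage.shape
        if populations is None:
            populations = np.repeat("P1", n)
        return GenotypeMatrix(
            individual_ids=[f"I{i}" for i in range(n)],
            locus_ids=[f"L{j}" for j in range(L)],
            populations=np.asarray(populations),
            dosage=dosage,
            depth=depth,
            **kw,
        )

    return build


@pytest.fixture
def two_deme_gm(make_gm):
    """Two demes of 50 with weak genome-wide differentiation (Fst~0.02) and
    one strongly differentiated focal locus (0.9 vs 0.1) at index 0."""
    rng = np.random.default_rng(0)
    L = 500
    pbar = rng.uniform(0.2, 0.8, L)
    fst = 0.02
    a, b = pbar * (1 - fst) / fst, (1 - pbar) * (1 - fst) / fst
    pA, pB = rng.beta(a, b), rng.beta(a, b)
    pA[0], pB[0] = 0.9, 0.1
    dosage = np.vstack([rng.binomial(2, pA, (50, L)), rng.binomial(2, pB, (50, L))])
    return make_gm(dosage, populations=np.repeat(["A", "B"], 50))


@pytest.fixture
def small_community():
    return CommunityTable(pd.DataFrame(
        [[10.0, 10.0, 80.0, 0.0],
         [5.0, 0.0, 5.0, 5.0],
         [0.0, 1.0, 0.0, 9.0]],
        index=["S1", "S2", "S3"], columns=["spA", "spB", "spC", "spD"]))


@pytest.fixture
def env_table():
    rng = np.random.default_rng(3)
    n = 12
    e = rng.normal(0, 1, n)
    return EnvironmentTable(pd.DataFrame(
        {"E": e, "X1": rng.normal(0, 1, n), "aspect": np.where(e > 0, "N", "S")},
        index=[f"S{i}" for i in range(n)]), categorical=["aspect"])
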
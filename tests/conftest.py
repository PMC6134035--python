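import numpy as np
import pytest

from fragdiv import GenotypeMatrix, simulate_balding_nichols
from fragdiv.synthetic import SyntheticStudyConfig, make_study_fixture


@pytest.fixture
def bn_matrix():
    """Small three-population multi-allelic matrix with known structure."""
    rng = np.random.default_rng(11)
    freqs = [rng.dirichlet([1.0] * 4) for _ in range(12)]
    return simulate_balding_nichols(freqs, [0.05, 0.1, 0.2], [15, 15, 15],
                                    seed=7, marker_kind="ssr_id")


@pytest.fixture
def two_pop_matrix():
    """Two populations, three loci, hand-laid genotypes incl. missing."""
    calls = np.array([
        [[0, 0], [0, 1], [-1, -1]],
        [[0, 1], [1, 1], [0, 0]],
        [[1, 1], [0, 0], [0, 1]],
        [[0, 0], [0, 1], [1, 1]],
    ], dtype=np.int32)
    inds = ["a1", "a2", "b1", "b2"]
    return GenotypeMatrix(
        individuals=inds,
        populations={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        regions={"A": "fragmented", "B": "fragmented"},
        loci=["L1", "L2", "L3"],
        marker_kinds=["ssr_id"] * 3,
        calls=calls,
    )


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down full fixture: complete design, few loci."""
    cfg = SyntheticStudyConfig(
        n_loci_ssr_length=6, n_loci_ssr_id=8, n_loci_snp_ti=30,
        n_loci_snp_tv=20, alleles_per_ssr_length=6, alleles_per_ssr_id=5,
        seed=42,
    )
    return make_study_fixture(cfg)
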
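import numpy as np
import pandas as pd
import pytest

from twinconn import Cohort, adjust_cohort, generate_study_cohort
from twinconn.atlas import NETWORK_NAMES, NetworkAtlas, canonical_atlas


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def atlas268():
    return canonical_atlas()


@pytest.fixture(scope="session")
def balanced_atlas40():
    """Ten networks of four nodes each — fair ground for network comparisons."""
    return NetworkAtlas(np.repeat(list(NETWORK_NAMES), 4))


@pytest.fixture(scope="session")
def small_cohort():
    """Adjusted two-zygosity cohort at desk scale (12 MZ + 8 DZ pairs, R=15)."""
    syn = generate_study_cohort(n_mz=12, n_dz=8, node_count=15, seed=42)
    return adjust_cohort(syn.cohort)


def make_cohort(g_by_pair, zygosity="MZ", edges=None, n_edges=3, seed=0):
    """Hand-built cohort: g_by_pair is a list of (g_member1, g_member2)."""
    rng = np.random.default_rng(seed)
    rows = []
    for p, (ga, gb) in enumerate(g_by_pair):
        for tag, g in (("A", ga), ("B", gb)):
            rows.append(
                {
                    "subject_id": f"S{p:03d}{tag}",
                    "pair_id": f"P{p:03d}",
                    "zygosity": zygosity,
                    "age": 25,
                    "gender": p % 2,
                    "g_raw": g,
                    "g_adjusted": g,
                }
            )
    n = 2 * len(g_by_pair)
    if edges is None:
        edges = rng.standard_normal((n, n_edges))
    return Cohort(pd.DataFrame(rows), edges)


@pytest.fixture
def pair_cohort_factory():
    return make_cohort
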
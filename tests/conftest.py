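import numpy as np
import pytest

from signedfc.connectivity import BinaryGraph


def graph_from_edges(n, edges):
    return BinaryGraph(n_nodes=n, edges=frozenset(tuple(sorted(e)) for e in edges))


def graph_from_adjacency(a):
    n = len(a)
    edges = frozenset(
        (i, j) for i in range(n) for j in range(i + 1, n) if a[i, j]
    )
    return BinaryGraph(n_nodes=n, edges=edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_cohort():
    """4-site cohort with a planted between-module group difference."""
    from signedfc.cohort import CohortSpec, SiteTemplate, generate_cohort

    spec = CohortSpec(
        n_regions=16,
        n_modules=4,
        within_module_corr=0.5,
        between_module_corr_hc=0.0,
        between_module_corr_asd=0.4,
        seed=11,
    )
    sites = [
        SiteTemplate(f"SITE{i}", 10, 10, 12.0 + i, 13.0 + i, 2.0, 2.0, n_timepoints=300)
        for i in range(4)
    ]
    return generate_cohort(spec, sites, seed=11)
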
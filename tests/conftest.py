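"""Shared fixtures: synthetic surfaces and their parametrisations.

Expensive products (Ricci flows, full parametrisations, registered
cohorts) are session-scoped so the suite computes each once.
"""

import numpy as np
import pytest

import femurmap as fm
from femurmap.pipeline import parametrise


@pytest.fixture(scope="session")
def femur():
    """Default (mirror-symmetric, jitter-free) femur fixture."""
    outer, inner, truth = fm.make_femur(fm.FemurSpec(n_vertices=2000))
    return outer, inner, truth


@pytest.fixture(scope="session")
def femur_param(femur):
    outer, _, _ = femur
    return parametrise(outer)


@pytest.fixture(scope="session")
def small_femur():
    outer, inner, truth = fm.make_femur(fm.FemurSpec(n_vertices=900, seed=4))
    return outer, inner, truth


@pytest.fixture(scope="session")
def challenge_params():
    """Three jittered subjects with differing neck/shaft lengths, parametrised."""
    specs = [
        fm.FemurSpec(n_vertices=1200, seed=s, shape_jitter=0.8,
                     shaft_length=55 + dl, neck_length=12 + dn)
        for s, (dl, dn) in enumerate([(0, 0), (8, 2), (-7, -2)])
    ]
    out = {}
    for i, spec in enumerate(specs):
        outer, inner, truth = fm.make_femur(spec)
        outer.fields["thickness"] = np.full(outer.n_vertices, 3.0)
        out[f"s{i}"] = (parametrise(outer), truth)
    return out


@pytest.fixture(scope="session")
def stats_template():
    """A ~1k-node femur used as the template graph for statistics tests."""
    outer, _, truth = fm.make_femur(fm.FemurSpec(n_vertices=1000))
    return outer, truth


def ring_distance(mesh, a: int, b: int) -> int:
    """Graph (1-ring) distance between two vertices."""
    import networkx as nx

    G = nx.Graph()
    G.add_edges_from(mesh.edges.tolist())
    return nx.shortest_path_length(G, int(a), int(b))
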
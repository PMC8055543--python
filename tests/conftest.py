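import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def triangle_lattice():
    from rigiperc.lattice import Lattice

    return Lattice(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.9]]),
                   [(0, 1), (1, 2), (0, 2)], L=2)


@pytest.fixture(scope="session")
def rhombus_cycle_lattice():
    """Four nodes on a 4-cycle: the minimal non-rigid closed topology."""
    from rigiperc.lattice import Lattice

    return Lattice(np.array([[0.0, 0.0], [1.0, 0.0], [1.3, 0.9], [0.3, 0.9]]),
                   [(0, 1), (1, 2), (2, 3), (0, 3)], L=2)


def random_graph(rng, n_lo=4, n_hi=12):
    """A random small framework with generic coordinates."""
    n = int(rng.integers(n_lo, n_hi + 1))
    coords = rng.random((n, 2)) * 10
    pairs = list(itertools.combinations(range(n), 2))
    m = int(rng.integers(max(2, n // 2), min(len(pairs), 2 * n) + 1))
    idx = rng.choice(len(pairs), size=m, replace=False)
    return coords, [pairs[i] for i in idx]


def rigidity_matrix(coords, edges):
    R = np.zeros((len(edges), 2 * len(coords)))
    for i, (u, v) in enumerate(edges):
        d = coords[u] - coords[v]
        R[i, 2 * u:2 * u + 2] = d
        R[i, 2 * v:2 * v + 2] = -d
    return R


def generic_rank(coords, edges):
    """Numerical rank of the generic rigidity matrix (independent-edge
    count oracle)."""
    if not edges:
        return 0
    s = np.linalg.svd(rigidity_matrix(coords, edges), compute_uv=False)
    return int((s > 1e-8 * s[0]).sum())


def flex_basis(coords, edges):
    """Orthonormal basis of infinitesimal motions (null space of the
    rigidity matrix)."""
    R = rigidity_matrix(coords, edges) if edges else np.zeros((1, 2 * len(coords)))
    _, s, vt = np.linalg.svd(R, full_matrices=True)
    rank = int((s > 1e-8 * max(s[0], 1e-30)).sum())
    return vt[rank:]


def pair_rigid_oracle(coords, basis, u, v):
    """True when no infinitesimal flex changes the u-v distance: the
    rank-based mutual-rigidity test."""
    d = coords[u] - coords[v]
    for f in basis:
        rel = f[2 * u:2 * u + 2] - f[2 * v:2 * v + 2]
        if abs(float(np.dot(rel, d))) > 1e-7 * max(1.0, np.linalg.norm(d)):
            return False
    return True
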
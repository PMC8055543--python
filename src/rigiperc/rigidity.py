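"""Generic 2D rigidity analysis of lattices via the pebble game.

A set of nodes forms a *rigid cluster* when no relative motion within the
set is possible without stretching or compressing a bond.  Generic rigidity
in 2D bar-joint frameworks is purely combinatorial (Laman's condition), and
the (2,3) pebble game decides it in near-linear time: each edge accepted by
the game is an independent constraint, and a framework region is rigid when
its constraints absorb all internal degrees of freedom.

The decomposition reported here lists the *maximal* rigid clusters (induced
subgraphs; a node can belong to several clusters as a shared joint), the
giant cluster fraction ``gc = S_GC / N`` — the order parameter of the
rigidity percolation transition — the second-cluster fraction, the floppy
node set, and the floppy-mode count ``F = 2N - 3 - |independent edges|``.
The minimal rigid structure is a triangle, so clusters have at least three
nodes; a bare bond leaves its endpoints floppy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pebble import decompose_rigid_clusters, run_pebble_game
from .lattice import Lattice

__all__ = [
    "PebbleState",
    "RigidityDecomposition",
    "pebble_game",
    "rigid_clusters",
    "floppy_modes",
    "spanning_cluster_ids",
    "finite_cluster_sizes",
]


@dataclass
class PebbleState:
    """Raw pebble-game state: slot targets, free counts, independence flags."""

    peb: np.ndarray
    free: np.ndarray
    independent: np.ndarray  # bool per edge, in the lattice's edge order

    @property
    def n_independent(self) -> int:
        return int(self.independent.sum())


@dataclass
class RigidityDecomposition:
    """Maximal rigid clusters of a lattice and derived order parameters."""

    n_nodes: int
    clusters: list[frozenset[int]]          # size >= 3, sorted by decreasing size
    floppy_nodes: frozenset[int]
    independent_edges: list[tuple[int, int]]
    floppy_modes: int
    edge_cluster: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def cluster_sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def gc_fraction(self) -> float:
        return len(self.clusters[0]) / self.n_nodes if self.clusters else 0.0

    @property
    def second_gc_fraction(self) -> float:
        return len(self.clusters[1]) / self.n_nodes if len(self.clusters) > 1 else 0.0

    def non_gc_sizes(self) -> list[int]:
        """Sizes of all rigid clusters except the giant cluster."""
        return [len(c) for c in self.clusters[1:]]


def pebble_game(lat: Lattice):
    """Classify the lattice's edges as independent or redundant.

    Returns ``(independent, redundant, state)``; the redundant set is
    matroid-determined and therefore does not depend on edge order.
    """
    edges = lat.edge_array()
    peb, free, indep = run_pebble_game(lat.n_nodes, edges)
    state = PebbleState(peb, free, indep)
    independent = [e for e, ok in zip(lat.edges, indep) if ok]
    redundant = [e for e, ok in zip(lat.edges, indep) if not ok]
    return independent, redundant, state


def _components(n: int, edges: np.ndarray) -> np.ndarray:
    parent = np.arange(n, dtype=np.int64)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for u, v in edges:
        ru, rv = find(int(u)), find(int(v))
        if ru != rv:
            parent[ru] = rv
    return np.array([find(i) for i in range(n)], dtype=np.int64)


def floppy_modes(lat: Lattice, state: PebbleState | None = None) -> int:
    """Number of internal zero-energy deformation modes (Maxwell count).

    For a connected lattice ``F = 2N - 3 - |independent edges|`` — the free
    pebbles left by the game minus the three rigid-body motions.  For a
    disconnected lattice the count is taken per connected component, with
    three trivial motions per component of two or more nodes and two
    (translations only) per isolated node.
    """
    if lat.n_nodes == 0:
        raise ValueError("empty lattice")
    edges = lat.edge_array()
    if state is None:
        _, _, state = pebble_game(lat)
    comp = _components(lat.n_nodes, edges)
    labels, counts = np.unique(comp, return_counts=True)
    trivial = int(np.where(counts >= 2, 3, 2).sum())
    return int(2 * lat.n_nodes - trivial - state.n_independent)


def spanning_cluster_ids(
    decomp: RigidityDecomposition,
    coords: np.ndarray,
    axis: int | None = None,
    tol: float = 0.5,
) -> set[int]:
    """Indices of rigid clusters that percolate across the patch.

    A cluster spans an axis when it reaches within ``tol`` (default half a
    bond length, robust to positional jitter) of both extremes of the node
    cloud along that axis.  With ``axis=None`` (default) a cluster counts
    as spanning — macroscopic, "giant" — when it spans either axis;
    passing 0 or 1 restricts to one direction (1 is the direction of force
    transmission in the shear protocol).
    """
    axes = (0, 1) if axis is None else (axis,)
    lims = [(coords[:, a].min(), coords[:, a].max()) for a in axes]
    out = set()
    for i, c in enumerate(decomp.clusters):
        pts = coords[list(c)]
        for a, (lo, hi) in zip(axes, lims):
            vals = pts[:, 0 if a == 0 else 1]
            if vals.min() <= lo + tol and vals.max() >= hi - tol:
                out.add(i)
                break
    return out


def finite_cluster_sizes(
    decomp: RigidityDecomposition,
    coords: np.ndarray,
    axis: int | None = None,
    tol: float = 0.5,
) -> list[int]:
    """Sizes of the non-percolating ("finite") rigid clusters.

    This is the pool entering the cluster-size statistics p(s): clusters
    spanning the patch — giant in the thermodynamic sense — are excluded;
    below the transition, where no cluster spans, every cluster counts.
    The pool's variance diverges at the critical point while its mean
    stays near 4 nodes.
    """
    span = spanning_cluster_ids(decomp, coords, axis, tol)
    return [len(c) for i, c in enumerate(decomp.clusters) if i not in span]


def rigid_clusters(lat: Lattice) -> RigidityDecomposition:
    """Decompose a lattice into its maximal rigid clusters.

    Clusters of fewer than three nodes (bare bonds) are not reported; nodes
    belonging to no reported cluster are floppy.  ``gc_fraction`` is 0 when
    no cluster exists.  Isolated nodes count in ``N`` for the gc
    normalization.
    """
    n = lat.n_nodes
    if n == 0:
        raise ValueError("empty lattice")
    edges = lat.edge_array()
    peb, free, indep = run_pebble_game(n, edges)
    n_indep = int(indep.sum())  # recorded before the decomposition mutates state
    edge_cl, memb_c, memb_v, n_memb, n_cl = decompose_rigid_clusters(
        n, edges, peb, free, indep
    )
    raw: dict[int, set[int]] = {}
    for c, v in zip(memb_c[:n_memb], memb_v[:n_memb]):
        raw.setdefault(int(c), set()).add(int(v))
    clusters = sorted(
        (frozenset(vs) for vs in raw.values() if len(vs) >= 3),
        key=lambda c: (-len(c), min(c) if c else 0),
    )
    covered: set[int] = set()
    for c in clusters:
        covered |= c
    floppy = frozenset(range(n)) - covered

    comp = _components(n, edges)
    labels, counts = np.unique(comp, return_counts=True)
    trivial = int(np.where(counts >= 2, 3, 2).sum())
    fmodes = int(2 * n - trivial - n_indep)

    keep = {c for c, vs in raw.items() if len(vs) >= 3}
    order = {c: i for i, c in enumerate(sorted(
        keep, key=lambda c: (-len(raw[c]), min(raw[c]))))}
    edge_cluster = {
        e: order[int(c)]
        for e, c in zip(lat.edges, edge_cl)
        if int(c) in order
    }
    independent = [e for e, ok in zip(lat.edges, indep) if ok]
    return RigidityDecomposition(
        n_nodes=n,
        clusters=clusters,
        floppy_nodes=floppy,
        independent_edges=independent,
        floppy_modes=fmodes,
        edge_cluster=edge_cluster,
    )
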
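"""Numba kernels for the (2,3) pebble game on 2D bar-joint frameworks.

State representation: every node owns two pebbles.  ``peb[2*x + s]`` holds
the node covered by slot ``s`` of node ``x`` (the pebble covers the graph
edge ``(x, covered)``, directed away from its owner) or ``-1`` when the
pebble is free; ``free[x]`` caches the number of free slots.  A pebble
search is a DFS over the directed pebble graph (out-degree at most two);
when it reaches a free pebble the path is reversed so the pebble arrives at
the search root.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_pebble_game", "decompose_rigid_clusters"]


@njit(cache=True)
def _search_rotate(peb, free, start, blocked, visited, stamp, prev_node, prev_slot, stack):
    """Bring one free pebble to ``start`` without visiting ``blocked``.

    Returns True on success; the pebble digraph is updated in place.
    """
    st = stamp[0] + 1
    stamp[0] = st
    visited[start] = st
    if blocked >= 0:
        visited[blocked] = st
    top = 0
    stack[top] = start
    top += 1
    found = np.int64(-1)
    while top > 0:
        top -= 1
        x = stack[top]
        for s in range(2):
            y = peb[2 * x + s]
            if y < 0 or visited[y] == st:
                continue
            visited[y] = st
            prev_node[y] = x
            prev_slot[y] = s
            if free[y] > 0:
                found = y
                top = 0
                break
            stack[top] = y
            top += 1
    if found < 0:
        return False
    z = found
    while z != start:
        x = prev_node[z]
        s = prev_slot[z]
        # slot s of x covered edge (x, z); cover it from z instead
        fs = 0 if peb[2 * z] < 0 else 1
        peb[2 * z + fs] = x
        peb[2 * x + s] = -1
        z = x
    free[found] -= 1
    free[start] += 1
    return True


@njit(cache=True)
def _gather(peb, free, u, v, want, visited, stamp, prev_node, prev_slot, stack):
    """Accumulate ``want`` free pebbles on the pair ``(u, v)``."""
    while free[u] + free[v] < want:
        moved = False
        if free[u] < 2:
            moved = _search_rotate(peb, free, u, v, visited, stamp, prev_node, prev_slot, stack)
        if not moved and free[v] < 2:
            moved = _search_rotate(peb, free, v, u, visited, stamp, prev_node, prev_slot, stack)
        if not moved:
            return False
    return True


@njit(cache=True)
def run_pebble_game(n, edges):
    """Play the (2,3) pebble game over ``edges`` in order.

    Returns ``(peb, free, indep)`` where ``indep[e]`` marks edges accepted
    as independent (a pebble covers them); the redundant set is
    matroid-determined and does not depend on the processing order.
    """
    m = edges.shape[0]
    peb = np.full(2 * n, -1, np.int64)
    free = np.full(n, 2, np.int64)
    indep = np.zeros(m, np.bool_)
    visited = np.zeros(n, np.int64)
    stamp = np.zeros(1, np.int64)
    prev_node = np.zeros(n, np.int64)
    prev_slot = np.zeros(n, np.int64)
    stack = np.zeros(n, np.int64)
    for e in range(m):
        u = edges[e, 0]
        v = edges[e, 1]
        if _gather(peb, free, u, v, 4, visited, stamp, prev_node, prev_slot, stack):
            indep[e] = True
            fs = 0 if peb[2 * u] < 0 else 1
            peb[2 * u + fs] = v
            free[u] -= 1
    return peb, free, indep


@njit(cache=True)
def decompose_rigid_clusters(n, edges, peb, free, indep):
    """Maximal rigid clusters after the pebble game (Jacobs–Thorpe style).

    For each unassigned independent edge ``(u, v)``: pin three free pebbles
    on its endpoints, then every node from which no free pebble is reachable
    (searches blocked at the pinned endpoints) is mutually rigid with the
    edge.  A failed reachability search certifies its whole visited set
    rigid; a successful one certifies only its root floppy, so the result is
    independent of the order in which nodes are probed.  Because a rigid
    cluster is a connected induced subgraph, candidates are probed by
    growing outward from the base edge along graph adjacency; nodes never
    reached by that frontier cannot belong to the cluster.

    Returns ``(edge_cluster, memb_cluster, memb_vertex, n_members,
    n_clusters)``: per-edge cluster ids and (cluster, vertex) membership
    pairs (a vertex may sit in several clusters as a shared joint).
    """
    m = edges.shape[0]
    # vertex -> incident edges (CSR)
    deg = np.zeros(n, np.int64)
    for e in range(m):
        deg[edges[e, 0]] += 1
        deg[edges[e, 1]] += 1
    ptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        ptr[i + 1] = ptr[i] + deg[i]
    inc = np.zeros(2 * m, np.int64)
    fill = ptr[:n].copy()
    for e in range(m):
        for x in (edges[e, 0], edges[e, 1]):
            inc[fill[x]] = e
            fill[x] += 1

    edge_cluster = np.full(m, -1, np.int64)
    visited = np.zeros(n, np.int64)
    stamp = np.zeros(1, np.int64)
    prev_node = np.zeros(n, np.int64)
    prev_slot = np.zeros(n, np.int64)
    stack = np.zeros(n, np.int64)
    visit_list = np.zeros(n, np.int64)
    rigid_mark = np.full(n, -1, np.int64)
    floppy_mark = np.full(n, -1, np.int64)
    queued_mark = np.full(n, -1, np.int64)
    queue = np.zeros(n + 4, np.int64)

    cap = n + 2 * m + 16
    memb_cluster = np.zeros(cap, np.int64)
    memb_vertex = np.zeros(cap, np.int64)
    n_members = 0
    n_clusters = 0

    for e0 in range(m):
        if edge_cluster[e0] >= 0 or not indep[e0]:
            continue
        u = edges[e0, 0]
        v = edges[e0, 1]
        _gather(peb, free, u, v, 3, visited, stamp, prev_node, prev_slot, stack)
        rid = n_clusters
        rigid_mark[u] = rid
        rigid_mark[v] = rid
        # frontier queue of candidate nodes: graph neighbours of the rigid set
        qhead = 0
        qtail = 0
        for x in (u, v):
            for p in range(ptr[x], ptr[x + 1]):
                f = inc[p]
                y = edges[f, 0] + edges[f, 1] - x
                if (rigid_mark[y] != rid and floppy_mark[y] != rid
                        and queued_mark[y] != rid):
                    queued_mark[y] = rid
                    queue[qtail] = y
                    qtail += 1
        while qhead < qtail:
            w = queue[qhead]
            qhead += 1
            if rigid_mark[w] == rid or floppy_mark[w] == rid:
                continue
            if free[w] > 0:
                floppy_mark[w] = rid
                continue
            st = stamp[0] + 1
            stamp[0] = st
            visited[u] = st
            visited[v] = st
            visited[w] = st
            nvis = 0
            visit_list[nvis] = w
            nvis += 1
            top = 0
            stack[top] = w
            top += 1
            success = False
            while top > 0:
                top -= 1
                x = stack[top]
                for s in range(2):
                    y = peb[2 * x + s]
                    if y < 0 or visited[y] == st:
                        continue
                    visited[y] = st
                    visit_list[nvis] = y
                    nvis += 1
                    if free[y] > 0:
                        success = True
                        top = 0
                        break
                    stack[top] = y
                    top += 1
            if success:
                floppy_mark[w] = rid
            else:
                for i in range(nvis):
                    z = visit_list[i]
                    if rigid_mark[z] == rid:
                        continue
                    rigid_mark[z] = rid
                    for p in range(ptr[z], ptr[z + 1]):
                        f = inc[p]
                        y = edges[f, 0] + edges[f, 1] - z
                        if (rigid_mark[y] != rid and floppy_mark[y] != rid
                                and queued_mark[y] != rid):
                            queued_mark[y] = rid
                            queue[qtail] = y
                            qtail += 1
        # collect cluster and assign its induced edges
        for w in range(n):
            if rigid_mark[w] != rid:
                continue
            memb_cluster[n_members] = rid
            memb_vertex[n_members] = w
            n_members += 1
            for p in range(ptr[w], ptr[w + 1]):
                f = inc[p]
                if edge_cluster[f] < 0:
                    a = edges[f, 0]
                    b = edges[f, 1]
                    if rigid_mark[a] == rid and rigid_mark[b] == rid:
                        edge_cluster[f] = rid
        n_clusters += 1

    return edge_cluster, memb_cluster[:n_members], memb_vertex[:n_members], n_members, n_clusters
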
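"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import rdnahomeo as r


@pytest.fixture(scope="session")
def small_cfg() -> r.SimConfig:
    """Desk-scale study conditions: short unit, moderate coverage."""
    return r.SimConfig(
        unit_length=1200,
        divergence=0.01,  # 12 diagnostic sites
        n_A=1700,
        n_C=1160,
        n_intra_A=3,
        n_intra_C=2,
        coverage=60.0,
        read_length=100,
        error_rate=0.0,
        target_genome_proportion=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def progenitors(small_cfg):
    return r.make_progenitor_pair(small_cfg)


# ---------------------------------------------------------------------------
# exhaustive dynamic-programming oracle for the mapper

def oracle_fit_align(read: str, ref: str, mismatch: int = 2, insertion: int = 3,
                     deletion: int = 3):
    """Full glocal DP over the whole reference: read global, ref flanks free.

    Returns (cost, identity, accept) where identity = matches / aligned
    columns and accept applies the 0.8 similarity gate.  Written as an
    exhaustive scan (no seeding, no band) so it is independent of the
    production mapper's search strategy.
    """
    rc = read.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    best = None
    for seq in (read, rc):
        res = _fit_dp(seq, ref, mismatch, insertion, deletion)
        if best is None or res[0] < best[0]:
            best = res
    cost, matches, columns = best
    identity = matches / columns if columns else 0.0
    return cost, identity, identity >= 0.8


def _fit_dp(read: str, ref: str, mis: int, ins: int, dele: int):
    q = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(ref.encode(), dtype=np.uint8)
    m, n = len(q), len(t)
    D = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        sub = D[i - 1, :-1] + np.where(t == q[i - 1], 0, mis)
        row = np.empty(n + 1, dtype=np.int64)
        row[0] = D[i - 1, 0] + ins
        row[1:] = np.minimum(sub, D[i - 1, 1:] + ins)
        for j in range(1, n + 1):  # deletion pass, deliberately explicit
            if row[j - 1] + dele < row[j]:
                row[j] = row[j - 1] + dele
        D[i] = row
    j = int(np.argmin(D[m]))
    i = m
    matches = columns = 0
    while i > 0:
        if j > 0 and D[i, j] == D[i - 1, j - 1] + (0 if t[j - 1] == q[i - 1] else mis):
            matches += int(t[j - 1] == q[i - 1])
            columns += 1
            i, j = i - 1, j - 1
        elif D[i, j] == D[i - 1, j] + ins:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return int(D[m].min()), matches, columns


# ---------------------------------------------------------------------------
# random additive trees for neighbour-joining consistency checks

def random_additive_case(rng: np.random.Generator, n_taxa: int):
    """A random unrooted binary tree with positive branch lengths.

    Returns (ids, distance_matrix, bipartitions) where the matrix is the
    tree's exact path-length metric and bipartitions are the non-trivial
    splits as frozensets excluding the lexicographically first taxon.
    """
    ids = [f"t{i}" for i in range(n_taxa)]
    adj: dict[int, dict[int, float]] = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def del_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    next_node = n_taxa  # internal node labels start after the leaves
    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, float(rng.uniform(0.05, 1.0)))
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        mid = next_node
        next_node += 1
        del_edge(u, v)
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(leaf, mid, float(rng.uniform(0.05, 1.0)))

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node].items():
                if nbr not in out:
                    out[nbr] = out[node] + w
                    stack.append(nbr)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        d = dists_from(i)
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = d[j]

    taxa = frozenset(ids)
    anchor = min(taxa)
    bipartitions = set()
    for u in adj:
        for v in adj[u]:
            if u < v and u >= n_taxa and v >= n_taxa:  # internal edge
                side_nodes = set()
                stack = [u]
                seen = {v}
                while stack:
                    node = stack.pop()
                    if node in seen:
                        continue
                    seen.add(node)
                    if node < n_taxa:
                        side_nodes.add(ids[node])
                    stack.extend(adj[node])
                side = frozenset(side_nodes)
                if anchor in side:
                    side = taxa - side
                if 2 <= len(side) <= n_taxa - 2:
                    bipartitions.add(side)
    return ids, D, bipartitions


def nj_bipartitions(tree, ids):
    from rdnahomeo.igs import _bipartitions

    return _bipartitions(tree, frozenset(ids))
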
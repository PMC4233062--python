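"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented with slow, obvious algorithms
that share no code with the package: exhaustive dynamic programming for
alignment scores, fine-grid scans for root finding, and explicit topology
enumeration for tree reconstruction.
"""
from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# local alignment (Smith-Waterman, affine gaps) -- plain cubic-ish DP

def sw_score_affine(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score; gap of length k costs open+(k-1)*extend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a (b consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + sub[a[i - 1], b[j - 1]]
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


# ---------------------------------------------------------------------------
# end-gap-free global alignment score (Gotoh), matching the duplication caller

def semiglobal_score(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                     gap_open: float = 5.0, gap_extend: float = 2.0) -> float:
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading end gaps
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
    # free trailing end gaps: best over last row and column, all states
    best = neg
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def semiglobal_stats(a: str, b: str, match: float = 2.0, mismatch: float = -3.0,
                     gap_open: float = 5.0, gap_extend: float = 2.0,
                     ) -> tuple[float, float]:
    """(coverage, similarity) from a full traceback of the end-gap-free
    global alignment: coverage = both-residue columns / longer length,
    similarity = identical columns / both-residue columns."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
    # locate the best end on the boundary (free trailing gaps)
    best = (neg, None)
    for i in range(n + 1):
        for state, V in (("M", M), ("X", X), ("Y", Y)):
            if V[i][m] > best[0]:
                best = (V[i][m], (i, m, state))
    for j in range(m + 1):
        for state, V in (("M", M), ("X", X), ("Y", Y)):
            if V[n][j] > best[0]:
                best = (V[n][j], (n, j, state))
    i, j, state = best[1]
    aligned_cols = matches = 0
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 and j == 0:
                break
            if M[i][j] == 0.0 and i == 0 and j == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            aligned_cols += 1
            matches += a[i - 1] == b[j - 1]
            prev = M[i][j] - s
            if i == 1 and j == 1 and abs(prev - 0.0) < 1e-9 and M[0][0] == 0.0:
                i, j, state = 0, 0, "M"
                continue
            for pstate, V in (("M", M), ("X", X), ("Y", Y)):
                if abs(V[i - 1][j - 1] - prev) < 1e-9:
                    i, j, state = i - 1, j - 1, pstate
                    break
            else:
                raise RuntimeError("traceback failed in M")
        elif state == "X":
            if j == 0:  # free leading gap region
                break
            for pstate, V, cost in (("M", M, gap_open), ("X", X, gap_extend),
                                    ("Y", Y, gap_open)):
                if abs(V[i - 1][j] - (X[i][j] + cost)) < 1e-9:
                    i, state = i - 1, pstate
                    break
            else:
                raise RuntimeError("traceback failed in X")
        else:  # Y
            if i == 0:
                break
            for pstate, V, cost in (("M", M, gap_open), ("Y", Y, gap_extend),
                                    ("X", X, gap_open)):
                if abs(V[i][j - 1] - (Y[i][j] + cost)) < 1e-9:
                    j, state = j - 1, pstate
                    break
            else:
                raise RuntimeError("traceback failed in Y")
    coverage = aligned_cols / max(n, m)
    similarity = matches / aligned_cols if aligned_cols else 0.0
    return coverage, similarity


# ---------------------------------------------------------------------------
# unrooted topology enumeration + least-squares additive fit

def enumerate_topologies(labels: list[str]):
    """All unrooted binary topologies as edge lists over labeled/internal nodes."""
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    base = [("internal0", labels[0]), ("internal0", labels[1]), ("internal0", labels[2])]
    trees = [base]
    for k, leaf in enumerate(labels[3:], start=1):
        new_trees = []
        for edges in trees:
            for idx in range(len(edges)):
                u, v = edges[idx]
                mid = f"internal{k}x{idx}"
                rest = edges[:idx] + edges[idx + 1 :]
                new_trees.append(rest + [(u, mid), (mid, v), (mid, leaf)])
        trees = new_trees
    return trees


def _leaf_paths(edges, labels):
    adj: dict[str, list[tuple[str, int]]] = {}
    for ei, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, ei))
        adj.setdefault(v, []).append((u, ei))

    def path_edges(src, dst):
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, used = stack.pop()
            if node == dst:
                return used
            for nxt, ei in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, used + [ei]))
        raise RuntimeError("disconnected tree")

    rows = []
    for x, y in itertools.combinations(labels, 2):
        row = np.zeros(len(edges))
        for ei in path_edges(x, y):
            row[ei] = 1.0
        rows.append(row)
    return np.array(rows)


def best_topology_least_squares(labels: list[str], dist: np.ndarray):
    """Exhaustively fit every unrooted topology; return the bipartition set of
    the topology with the smallest least-squares residual."""
    d_vec = np.array([dist[i, j] for i, j in
                      itertools.combinations(range(len(labels)), 2)])
    best = None
    for edges in enumerate_topologies(labels):
        A = _leaf_paths(edges, labels)
        lengths, residual, *_ = np.linalg.lstsq(A, d_vec, rcond=None)
        res = float(((A @ lengths - d_vec) ** 2).sum())
        if best is None or res < best[0]:
            best = (res, edges)
    _, edges = best
    return topology_bipartitions(edges, labels)


def topology_bipartitions(edges, labels) -> set[frozenset]:
    """Non-trivial bipartitions induced by internal edges of an edge list."""
    all_set = frozenset(labels)
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    parts = set()
    for u, v in edges:
        # leaves reachable from v without crossing (u, v)
        stack, seen = [v], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node in labels:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side_f = frozenset(side)
        other = all_set - side_f
        if len(side_f) >= 2 and len(other) >= 2:
            parts.add(frozenset((side_f, other)))
    return parts


def random_additive_tree(labels: list[str], rng: np.random.Generator):
    """Random unrooted binary topology with positive branch lengths; returns
    (distance matrix, bipartition set)."""
    topologies = None
    # build by random sequential insertion instead of enumerating everything
    edges = [("i0", labels[0]), ("i0", labels[1]), ("i0", labels[2])]
    for k, leaf in enumerate(labels[3:], start=1):
        idx = int(rng.integers(len(edges)))
        u, v = edges.pop(idx)
        mid = f"i{k}"
        edges.extend([(u, mid), (mid, v), (mid, leaf)])
    lengths = rng.uniform(0.5, 3.0, size=len(edges))
    A = _leaf_paths(edges, labels)
    d_vec = A @ lengths
    n = len(labels)
    dist = np.zeros((n, n))
    for (row, (i, j)) in zip(d_vec, itertools.combinations(range(n), 2)):
        dist[i, j] = dist[j, i] = row
    return dist, topology_bipartitions(edges, labels)


# ---------------------------------------------------------------------------
# fine-grid pI scan

def grid_pi(charge_fn, protein: str, step: float = 1e-4) -> float:
    phs = np.arange(0.0, 14.0 + step, step)
    charges = np.array([charge_fn(protein, ph) for ph in phs])
    return float(phs[np.argmin(np.abs(charges))])
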
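"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive and written from the definitions, not
from the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# exhaustive global alignment


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def _gap_run_cost(row: str, gap_open: float, gap_extend: float) -> float:
    cost = 0.0
    run = 0
    for ch in row + "X":
        if ch == "-":
            run += 1
        elif run:
            cost += gap_open + run * gap_extend
            run = 0
    return cost


def score_alignment(row_a, row_b, score_fn, gap_open, gap_extend) -> float:
    total = 0.0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            total += score_fn(x, y)
    total -= _gap_run_cost(row_a, gap_open, gap_extend)
    total -= _gap_run_cost(row_b, gap_open, gap_extend)
    return total


def best_alignment_score(a, b, score_fn, gap_open, gap_extend) -> float:
    return max(
        score_alignment(ra, rb, score_fn, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


# ---------------------------------------------------------------------------
# transitive closure grouping


def closure_components(n: int, edges: set[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected components via boolean-matrix transitive closure."""
    reach = np.eye(n, dtype=bool)
    for i, j in edges:
        reach[i, j] = reach[j, i] = True
    for _ in range(n):
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(np.where(reach[i])[0].tolist())
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# naive UPGMA (recomputes cluster distances from the original matrix)


def naive_upgma(d: np.ndarray):
    """Merge list [(a, b, height, size)]; distances between clusters are the
    plain average over all original leaf pairs, recomputed each step."""
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best, pair = math.inf, None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                v = float(
                    np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if v < best - 1e-15:
                    best, pair = v, (a, b)
        a, b = pair
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, best, len(clusters[next_id])))
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# random additive trees for NJ recovery


def random_binary_tree(n_leaves: int, rng: np.random.Generator):
    """Unrooted binary tree as (edges dict {frozenset(u,v): length}, leaves)."""
    # start from a 3-star
    edges = {}
    center = "I0"
    leaves = [f"L{i}" for i in range(n_leaves)]
    for l in leaves[:3]:
        edges[frozenset((center, l))] = float(rng.uniform(0.1, 1.0))
    internal = 1
    for l in leaves[3:]:
        target = list(edges)[rng.integers(0, len(edges))]
        ln = edges.pop(target)
        u, v = tuple(target)
        mid = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.25, 0.75))
        edges[frozenset((u, mid))] = ln * split
        edges[frozenset((mid, v))] = ln * (1 - split)
        edges[frozenset((mid, l))] = float(rng.uniform(0.1, 1.0))
    return edges, leaves


def tree_distances(edges: dict, leaves: list[str]) -> np.ndarray:
    adj: dict[str, list[tuple[str, float]]] = {}
    for e, ln in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    n = len(leaves)
    d = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nxt, ln in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + ln
                    stack.append(nxt)
        for j, other in enumerate(leaves):
            d[i, j] = dist[other]
    return d


def tree_splits(edges: dict, leaves: list[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions (one side) induced by internal edges."""
    adj: dict[str, list[str]] = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    leafset = set(leaves)
    for e in edges:
        u, v = tuple(e)
        # leaves on u's side when edge removed
        side = set()
        stack = [u]
        seen = {u, v}
        while stack:
            cur = stack.pop()
            if cur in leafset:
                side.add(cur)
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset(min((side, leafset - side), key=sorted)))
    return splits


def rooted_tree_splits(root) -> set[frozenset[str]]:
    """Bipartitions of a package TreeNode (unrooted interpretation)."""
    all_leaves = set(root.leaf_names())
    splits = set()

    def walk(node):
        names = set()
        if node.is_leaf():
            return {node.name}
        for c in node.children:
            names |= walk(c)
        if 1 < len(names) < len(all_leaves) - 1:
            splits.add(frozenset(min((names, all_leaves - names), key=sorted)))
        return names

    walk(root)
    return splits


def rooted_leaf_distances(root, leaves: list[str]) -> np.ndarray:
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}

    def collect(node):
        names[id(node)] = node.name
        for c in node.children:
            adj.setdefault(id(node), []).append((id(c), c.length))
            adj.setdefault(id(c), []).append((id(node), c.length))
            collect(c)

    collect(root)
    by_name = {v: k for k, v in names.items() if v}
    n = len(leaves)
    d = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        start = by_name[leaf]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, ln in adj.get(cur, []):
                if nxt not in dist:
                    dist[nxt] = dist[cur] + ln
                    stack.append(nxt)
        for j, other in enumerate(leaves):
            d[i, j] = dist[by_name[other]]
    return d


# ---------------------------------------------------------------------------
# exhaustive strain decomposition (all binary matrices, LP per matrix)


def exhaustive_min_strains(observed: np.ndarray, epsilon: float, k_max: int):
    """Smallest k with any binary genes-x-k matrix (nonempty rows) and a
    positive abundance vector on the simplex whose Chebyshev residual is at
    most epsilon.  Returns (k, residual) or (None, best_residual)."""
    g = len(observed)
    best_any = math.inf
    for k in range(1, k_max + 1):
        rows = [
            np.array(bits, dtype=float)
            for bits in itertools.product((0, 1), repeat=k)
            if any(bits)
        ]
        best_k = math.inf
        for choice in itertools.product(range(len(rows)), repeat=g):
            M = np.array([rows[c] for c in choice])
            res = _cheb_lp(M, observed)
            if res is not None and res < best_k:
                best_k = res
        best_any = min(best_any, best_k)
        if best_k <= epsilon + 1e-12:
            return k, best_k
    return None, best_any


def _cheb_lp(M: np.ndarray, v: np.ndarray):
    g, k = M.shape
    c = np.zeros(k + 1)
    c[-1] = 1.0
    A_ub = np.block([[M, -np.ones((g, 1))], [-M, -np.ones((g, 1))]])
    b_ub = np.concatenate([v, -v])
    A_eq = np.zeros((1, k + 1))
    A_eq[0, :k] = 1.0
    r = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                bounds=[(1e-6, 1.0)] * k + [(0, None)], method="highs")
    return float(r.x[-1]) if r.success else None
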
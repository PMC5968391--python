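"""Neighbor-joining trees, midpoint rooting and Newick I/O.

Distances for tree building are p-distances (1 - PID); no multiple-hit
correction is applied.  Negative NJ branch lengths are clamped to zero and
the deficit moved to the sibling branch.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TreeNode", "nj_tree", "midpoint_root", "to_newick", "parse_newick",
           "write_newick", "read_newick", "distance_matrix_from_pid"]


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent; ignored at the root
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    # --- structural equality up to child order -------------------------------
    def canonical(self, ndigits: int = 9) -> tuple:
        if self.is_leaf():
            return ("leaf", self.name, round(self.length, ndigits))
        kids = tuple(sorted(c.canonical(ndigits) for c in self.children))
        return ("node", round(self.length, ndigits), kids)

    def same_as(self, other: "TreeNode", ndigits: int = 9) -> bool:
        return self.canonical(ndigits) == other.canonical(ndigits)

    # --- undirected edge view ------------------------------------------------
    def edges(self):
        """Yield (parent, child, length) over the rooted representation."""
        for c in self.children:
            yield self, c, c.length
            yield from c.edges()


def distance_matrix_from_pid(pid_values: np.ndarray) -> np.ndarray:
    """p-distance matrix 1 - PID with an exactly zero diagonal."""
    d = 1.0 - np.asarray(pid_values, dtype=float)
    np.fill_diagonal(d, 0.0)
    return d


def nj_tree(ids: list[str], d: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining from a distance matrix.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; ties break on the lowest (row, column) index.  Returns an
    unrooted tree represented with a trifurcating root.
    """
    d = np.asarray(d, dtype=float).copy()
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match id count")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("negative distances are not allowed")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) tie-break via lexicographic argmin scan
        best = np.inf
        bi = bj = -1
        for a in range(k):
            for b in range(a + 1, k):
                if q[a, b] < best - 1e-15:
                    best, bi, bj = q[a, b], a, b
        i, j = active[bi], active[bj]
        dij = d[i, j]
        vi = 0.5 * dij + (r[bi] - r[bj]) / (2 * (k - 2))
        vj = dij - vi
        if vi < 0:
            vi, vj = 0.0, dij
        elif vj < 0:
            vi, vj = dij, 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = vi, vj
        new = TreeNode(children=[ni, nj_])
        nodes.append(new)
        u = len(nodes) - 1
        # distances of the new cluster to remaining actives
        newrow = np.zeros(len(nodes))
        for a in active:
            if a in (i, j):
                continue
            newrow[a] = 0.5 * (d[i, a] + d[j, a] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[u, : u] = newrow[: u]
        d[: u, u] = newrow[: u]
        active = [a for a in active if a not in (i, j)] + [u]

    # resolve the final three clusters around a central node
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, v in zip((nodes[a], nodes[b], nodes[c]), (va, vb, vc)):
        node.length = max(v, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------------------
# midpoint rooting


def _adjacency(root: TreeNode) -> dict[int, list[tuple[int, float]]]:
    adj: dict[int, list[tuple[int, float]]] = {}
    for parent, child, length in root.edges():
        adj.setdefault(id(parent), []).append((id(child), length))
        adj.setdefault(id(child), []).append((id(parent), length))
    return adj


def _nodes_by_id(root: TreeNode) -> dict[int, TreeNode]:
    out = {id(root): root}
    for _, child, _ in root.edges():
        out[id(child)] = child
    return out


def _path(adj, start: int, goal: int) -> list[tuple[int, float]]:
    """Path as [(node, edge length to previous node)] starting at start."""
    stack = [(start, None)]
    prev: dict[int, tuple[int, float] | None] = {start: None}
    while stack:
        cur, _ = stack.pop()
        if cur == goal:
            break
        for nxt, ln in adj[cur]:
            if nxt not in prev:
                prev[nxt] = (cur, ln)
                stack.append((nxt, None))
    path = []
    cur = goal
    while cur is not None:
        entry = prev[cur]
        path.append((cur, entry[1] if entry else 0.0))
        cur = entry[0] if entry else None
    return list(reversed(path))


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    adj = _adjacency(tree)
    by_id = _nodes_by_id(tree)

    # all-pairs leaf distances (n is small in this pipeline)
    def dist_from(start: int) -> dict[int, float]:
        out = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, ln in adj[cur]:
                if nxt not in out:
                    out[nxt] = out[cur] + ln
                    stack.append(nxt)
        return out

    best = (-1.0, None, None)
    leaf_ids = sorted((l.name, id(l)) for l in leaves)
    for name_a, ida in leaf_ids:
        dmap = dist_from(ida)
        for name_b, idb in leaf_ids:
            if name_b <= name_a:
                continue
            if dmap[idb] > best[0] + 1e-15:
                best = (dmap[idb], ida, idb)
    diameter, ida, idb = best
    if diameter <= 0:
        warnings.warn("tree has zero total length; rooting at an arbitrary node",
                      RuntimeWarning, stacklevel=2)
        return _reroot(by_id, adj, id(tree), None, 0.0)

    half = diameter / 2.0
    path = _path(adj, ida, idb)
    acc = 0.0
    for idx in range(1, len(path)):
        node_id, ln = path[idx]
        if acc + ln >= half - 1e-12:
            # midpoint lies on edge (path[idx-1][0], node_id)
            from_prev = half - acc
            if abs(from_prev) < 1e-12:
                return _reroot(by_id, adj, path[idx - 1][0], None, 0.0)
            if abs(ln - from_prev) < 1e-12:
                return _reroot(by_id, adj, node_id, None, 0.0)
            return _reroot(by_id, adj, path[idx - 1][0], node_id,
                           from_prev, edge_len=ln)
        acc += ln
    raise AssertionError("midpoint not found on diameter path")


def _reroot(by_id, adj, anchor: int, other: int | None, split_at: float,
            edge_len: float = 0.0) -> TreeNode:
    """Rebuild a rooted tree. If other is given, the root splits the
    anchor-other edge at distance split_at from anchor."""

    def build(cur: int, parent: int | None, length: float,
              skip_edge: tuple[int, int] | None) -> TreeNode:
        orig = by_id[cur]
        node = TreeNode(name=orig.name, length=length)
        for nxt, ln in sorted(adj[cur], key=lambda t: _sort_key(by_id[t[0]])):
            if nxt == parent:
                continue
            if skip_edge and {cur, nxt} == set(skip_edge):
                continue
            node.children.append(build(nxt, cur, ln, skip_edge))
        return node

    def _sort_key(n: TreeNode):
        return (0, n.name) if n.name else (1, "")

    if other is None:
        root = build(anchor, None, 0.0, None)
        root.length = 0.0
        return root
    root = TreeNode()
    root.children.append(build(anchor, None, split_at, (anchor, other)))
    root.children.append(build(other, None, edge_len - split_at, (anchor, other)))
    return root


def leaf_depths(root: TreeNode) -> dict[str, float]:
    out: dict[str, float] = {}

    def walk(node: TreeNode, depth: float) -> None:
        if node.is_leaf():
            out[node.name] = depth
        for c in node.children:
            walk(c, depth + c.length)

    walk(root, 0.0)
    return out


# ---------------------------------------------------------------------------
# Newick

_META = set("()[]{}:;,'\" \t\n")


def _fmt_label(name: str) -> str:
    if any(ch in _META for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(root: TreeNode, decimals: int = 6) -> str:
    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf():
            s = _fmt_label(node.name or "")
        else:
            s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.name:
                s += _fmt_label(node.name)
        if not top:
            s += f":{node.length:.{decimals}f}"
        return s

    return fmt(root, True) + ";"


def write_newick(root: TreeNode, path, decimals: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(root, decimals) + "\n")


def parse_newick(text: str) -> TreeNode:
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        node.name = parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", s[pos:])
            if not m:
                raise ValueError(f"bad branch length at offset {pos}")
            node.length = float(m.group(0))
            pos += m.end()
        return node

    def parse_label() -> str | None:
        nonlocal pos
        if pos >= len(s):
            return None
        if s[pos] == "'":
            pos += 1
            out = []
            while True:
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        m = re.match(r"[^(),:;]+", s[pos:])
        if m:
            pos += m.end()
            return m.group(0)
        return None

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing Newick content at offset {pos}")
    return root


def read_newick(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())
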
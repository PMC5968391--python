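"""Ortholog-group assignment from pairwise percent identity.

Groups are single-linkage connected components of the graph whose edges join
sequence pairs with PID strictly above the threshold (default 0.90).
Singleton components are reported as "ungrouped".  A reference registry of
known group labels can be supplied; unlabeled components receive new numeric
labels continuing past the largest reference number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .seqalign import AlignParams, SequenceSet, default_params, global_align

__all__ = ["PidMatrix", "OrthologGroup", "OrthologAssignment", "pid_matrix",
           "assign_ortholog_groups", "read_registry", "write_membership"]


@dataclass
class PidMatrix:
    """Symmetric matrix of pairwise PID values with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("PID matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("PID matrix must have unit diagonal")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("PID values must lie in [0, 1]")
        self.values = v

    def pid(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def pid_matrix(seqs: SequenceSet, params: AlignParams | None = None) -> PidMatrix:
    """Align all n(n-1)/2 pairs and collect PID into a symmetric matrix."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a PID matrix")
    if params is None:
        params = default_params(seqs.molecule)
    n = len(seqs)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = global_align(seqs[i], seqs[j], params)
            except Exception as exc:  # annotate which pair failed
                raise RuntimeError(
                    f"alignment failed for pair ({seqs[i].id}, {seqs[j].id}): {exc}"
                ) from exc
            vals[i, j] = vals[j, i] = r.pid
    return PidMatrix(ids=list(seqs.ids), values=vals)


@dataclass
class OrthologGroup:
    label: str
    members: list[str]
    provenance: str  # "reference" | "new"
    min_pid: float


@dataclass
class OrthologAssignment:
    membership: dict[str, str]
    og_registry: dict[str, OrthologGroup]
    ungrouped: set[str]
    threshold: float = 0.90

    @property
    def n_groups(self) -> int:
        return len(self.og_registry)


_LABEL_NUM = re.compile(r"(\d+)")


def _label_number(label: str) -> int | None:
    m = _LABEL_NUM.search(label)
    return int(m.group(1)) if m else None


def assign_ortholog_groups(
    m: PidMatrix,
    threshold: float = 0.90,
    reference: dict[str, str] | None = None,
) -> OrthologAssignment:
    """Cluster sequences into ortholog groups at PID strictly above threshold.

    Components containing reference-labeled members inherit that label; a
    component with two different reference labels is a conflict error.  New
    labels are ``OG<k>`` with k continuing past the maximum reference number,
    assigned in order of the alphabetically smallest member id.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly in (0, 1)")
    reference = reference or {}
    n = len(m.ids)

    # union-find over the strict-threshold graph
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if m.values[i, j] > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    components = [sorted(m.ids[i] for i in idx) for idx in comps.values()]
    components.sort(key=lambda members: members[0])

    ungrouped = {c[0] for c in components if len(c) == 1}
    multi = [c for c in components if len(c) > 1]

    max_ref = 0
    for label in reference.values():
        num = _label_number(label)
        if num is not None:
            max_ref = max(max_ref, num)

    membership: dict[str, str] = {}
    registry: dict[str, OrthologGroup] = {}
    next_new = max_ref + 1
    for members in multi:
        labels = sorted({reference[s] for s in members if s in reference})
        if len(labels) > 1:
            raise ValueError(
                f"ortholog group conflict: members {members} carry reference "
                f"labels {labels}"
            )
        if labels:
            label, provenance = labels[0], "reference"
        else:
            label, provenance = f"OG{next_new}", "new"
            next_new += 1
        idx = [m.ids.index(s) for s in members]
        sub = m.values[np.ix_(idx, idx)]
        min_pid = float(sub[np.triu_indices(len(idx), k=1)].min())
        group = OrthologGroup(label=label, members=members, provenance=provenance,
                              min_pid=min_pid)
        if label in registry:
            raise ValueError(f"reference label {label!r} spans two components")
        registry[label] = group
        for s in members:
            membership[s] = label

    return OrthologAssignment(
        membership=membership,
        og_registry=registry,
        ungrouped=ungrouped,
        threshold=threshold,
    )


def read_registry(path) -> dict[str, str]:
    """Read a TSV of (sequence_id, og_label) into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, label = line.split("\t")[:2]
            if seq_id == "sequence_id":
                continue
            out[seq_id] = label
    return out


def write_membership(assignment: OrthologAssignment, path) -> None:
    """Write a TSV of (sequence_id, og_label) with 'ungrouped' singletons."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tog_label\n")
        for seq_id in sorted(assignment.membership):
            fh.write(f"{seq_id}\t{assignment.membership[seq_id]}\n")
        for seq_id in sorted(assignment.ungrouped):
            fh.write(f"{seq_id}\tungrouped\n")
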
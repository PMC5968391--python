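"""rdhA/16S ratio fingerprints, abundance bins and two-way clustering.

Each sample's fingerprint is the vector of gene copies divided by the 16S
copies of the same sample; since the organism carries a single 16S copy per
genome the ratio approximates the fraction of genomes carrying that gene.
Censoring: a gene below its MDL is "below detection" (an upper bound, never
zero); a sample whose 16S is below the MDL has an undefined profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .qpcr import Measurement

__all__ = [
    "Censor",
    "RatioProfile",
    "BINS",
    "Dendrogram",
    "compute_ratios",
    "bin_ratio",
    "pearson_similarity",
    "upgma",
    "cophenetic_matrix",
    "cut_dendrogram",
    "heatmap_table",
    "dendrogram_to_newick",
]

SIXTEEN_S = "Dhc_16S"

#: floor imputed for censored entries on the log10 scale (decade below the
#: smallest heatmap bin edge)
LOG_FLOOR = 1e-4


class Censor(str, Enum):
    BELOW_DETECTION = "below_detection"
    UNDEFINED = "undefined"


@dataclass
class RatioProfile:
    sample_id: str
    values: dict[str, float] = field(default_factory=dict)
    below_detection: dict[str, float] = field(default_factory=dict)  # gene -> bound
    undefined: bool = False
    dhc_16s_copies: float = float("nan")
    metadata: dict = field(default_factory=dict)
    gt_one: set[str] = field(default_factory=set)  # ratios > 1, flagged

    def genes(self) -> list[str]:
        return sorted(set(self.values) | set(self.below_detection))

    def state(self, gene: str) -> float | Censor:
        if self.undefined:
            return Censor.UNDEFINED
        if gene in self.values:
            return self.values[gene]
        if gene in self.below_detection:
            return Censor.BELOW_DETECTION
        return Censor.UNDEFINED


def compute_ratios(
    measurements: list[Measurement],
    sixteen_s_target: str = SIXTEEN_S,
    metadata: dict | None = None,
) -> RatioProfile:
    """Build one sample's ratio fingerprint from its measurements."""
    samples = {m.sample_id for m in measurements}
    if len(samples) != 1:
        raise ValueError(f"measurements span several samples: {sorted(samples)}")
    sample_id = samples.pop()
    ref = [m for m in measurements if m.target == sixteen_s_target]
    if not ref:
        raise ValueError(f"sample {sample_id!r} lacks a {sixteen_s_target} measurement")
    ref = ref[0]
    profile = RatioProfile(sample_id=sample_id, metadata=metadata or {})
    if ref.censored:
        profile.undefined = True
        return profile
    profile.dhc_16s_copies = ref.copies_per_unit
    for m in measurements:
        if m.target == sixteen_s_target:
            continue
        if m.censored:
            profile.below_detection[m.target] = m.mdl_per_unit / ref.copies_per_unit
        else:
            ratio = m.copies_per_unit / ref.copies_per_unit
            profile.values[m.target] = ratio
            if ratio > 1:
                profile.gt_one.add(m.target)
    return profile


BINS = ["gt_0.6", "0.1_to_0.6", "0.01_to_0.1", "0.001_to_0.01", "lt_0.001", "nd"]
_EDGES = [0.6, 0.1, 0.01, 0.001]


def bin_ratio(rho: float | Censor | None) -> str:
    """Half-open decade bins, lower edge inclusive; censored entries -> 'nd'."""
    if rho is None or isinstance(rho, Censor):
        return "nd"
    if rho < 0:
        raise ValueError(f"negative ratio {rho}")
    if rho >= 0.6:
        return "gt_0.6"
    if rho >= 0.1:
        return "0.1_to_0.6"
    if rho >= 0.01:
        return "0.01_to_0.1"
    if rho >= 0.001:
        return "0.001_to_0.01"
    return "lt_0.001"


def _log_matrix(profiles: list[RatioProfile]) -> tuple[list[str], list[str], np.ndarray]:
    """samples x genes matrix of log10 ratios; NaN where undefined."""
    genes = sorted({g for p in profiles for g in p.genes()})
    out = np.full((len(profiles), len(genes)), np.nan)
    for i, p in enumerate(profiles):
        if p.undefined:
            continue
        for j, g in enumerate(genes):
            if g in p.values:
                out[i, j] = math.log10(max(p.values[g], LOG_FLOOR))
            elif g in p.below_detection:
                out[i, j] = math.log10(LOG_FLOOR)
    return [p.sample_id for p in profiles], genes, out


def _pairwise_pearson(mat: np.ndarray, labels: list[str]) -> np.ndarray:
    n = mat.shape[0]
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if mask.sum() < 2:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) shares fewer than 2 defined entries"
                )
            x, y = mat[i, mask], mat[j, mask]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                rij = 1.0 if np.allclose(x, y) else 0.0
            else:
                rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
    return r


def pearson_similarity(
    profiles: list[RatioProfile], axis: str = "samples"
) -> tuple[list[str], np.ndarray]:
    """Pearson r on log10 ratios, pairwise-complete over defined entries.

    Censored entries are imputed at the 1e-4 floor; undefined profiles
    contribute nothing.  Returns (labels, similarity matrix r); the
    clustering distance is 1 - r.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    sample_ids, genes, mat = _log_matrix(profiles)
    if axis == "genes":
        mat = mat.T
        labels = genes
    else:
        labels = sample_ids
    if len(labels) < 2:
        raise ValueError(f"need >= 2 items on axis {axis!r}")
    return labels, _pairwise_pearson(mat, labels)


@dataclass
class Dendrogram:
    """UPGMA merge tree over labeled items.

    ``merges`` lists (cluster_a, cluster_b, height, size) with leaves indexed
    0..n-1 and merged clusters n, n+1, ... in creation order (scipy linkage
    convention).  ``similarity_percent`` maps each merge to 100*(1-height).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]

    @property
    def similarity_percent(self) -> list[float]:
        return [100.0 * (1.0 - h) for _, _, h, _ in self.merges]

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def upgma(labels: list[str], d: np.ndarray) -> Dendrogram:
    """Classic UPGMA: merge the closest pair; the distance of a merged
    cluster to any other is the member-count-weighted arithmetic mean.
    Ties break on the lowest (row, column) index pair."""
    d = np.asarray(d, dtype=float).copy()
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 items")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")

    # cluster bookkeeping: id -> (members, dict of distances keyed by other id)
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        best = math.inf
        pair = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                v = get(a, b)
                if v < best - 1e-15:
                    best, pair = v, (a, b)
        a, b = pair
        size = sizes[a] + sizes[b]
        new = next_id
        next_id += 1
        for c in active:
            if c in (a, b):
                continue
            v = (sizes[a] * get(a, c) + sizes[b] * get(b, c)) / size
            dist[(min(c, new), max(c, new))] = v
        active -= {a, b}
        active.add(new)
        sizes[new] = size
        children[new] = (a, b)
        merges.append((a, b, best, size))

    def order(cid: int) -> list[int]:
        if cid < n:
            return [cid]
        a, b = children[cid]
        return order(a) + order(b)

    return Dendrogram(labels=list(labels), merges=merges, leaf_order=order(next_id - 1))


def cophenetic_matrix(dg: Dendrogram) -> np.ndarray:
    """Cophenetic distances implied by the merge heights."""
    n = len(dg.labels)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    out = np.zeros((n, n))
    next_id = n
    for a, b, h, _ in dg.merges:
        for i in members[a]:
            for j in members[b]:
                out[i, j] = out[j, i] = h
        members[next_id] = members[a] + members[b]
        next_id += 1
    return out


def cut_dendrogram(dg: Dendrogram, n_clusters: int) -> dict[str, int]:
    """Flat cluster labels from keeping the first n - n_clusters merges."""
    n = len(dg.labels)
    if not (1 <= n_clusters <= n):
        raise ValueError("n_clusters out of range")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    for a, b, _, _ in dg.merges[: n - n_clusters]:
        members[next_id] = members[a] + members[b]
        next_id += 1
    top = set(members)
    for a, b, _, _ in dg.merges[: n - n_clusters]:
        top.discard(a)
        top.discard(b)
    out = {}
    for k, cid in enumerate(sorted(top)):
        for leaf in members[cid]:
            out[dg.labels[leaf]] = k
    return out


def dendrogram_to_newick(dg: Dendrogram, decimals: int = 6) -> str:
    """Ultrametric Newick; a merge at height h sits at depth h/2."""
    n = len(dg.labels)
    depth = {i: 0.0 for i in range(n)}
    text = {i: dg.labels[i] for i in range(n)}
    next_id = n
    for a, b, h, _ in dg.merges:
        depth[next_id] = h / 2.0
        la = depth[next_id] - depth[a]
        lb = depth[next_id] - depth[b]
        text[next_id] = (
            f"({text[a]}:{la:.{decimals}f},{text[b]}:{lb:.{decimals}f})"
        )
        next_id += 1
    return text[next_id - 1] + ";"


def heatmap_table(
    profiles: list[RatioProfile],
    gene_order: list[str] | None = None,
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Genes x samples grid of bin labels with raw ratios alongside.

    Row/column order comes from the dendrogram leaf orders, so the output is
    invariant to the order profiles are passed in.
    """
    by_id = {p.sample_id: p for p in profiles}
    if sample_order is None:
        sample_order = sorted(by_id)
    all_genes = sorted({g for p in profiles for g in p.genes()})
    if gene_order is None:
        gene_order = all_genes
    rows = []
    for g in gene_order:
        for s in sample_order:
            state = by_id[s].state(g)
            rows.append(
                {
                    "gene": g,
                    "sample_id": s,
                    "ratio": state if isinstance(state, float) else float("nan"),
                    "bin": bin_ratio(state),
                }
            )
    return pd.DataFrame(rows)


def heatmap_image(table: pd.DataFrame, path) -> None:
    """Optional PNG rendering of a heatmap table (log10 ratio scale)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="gene", columns="sample_id", values="ratio")
    with np.errstate(divide="ignore"):
        vals = np.log10(pivot.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(1 + 0.5 * pivot.shape[1], 1 + 0.4 * pivot.shape[0]))
    im = ax.imshow(vals, aspect="auto", cmap="viridis")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="log10 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
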
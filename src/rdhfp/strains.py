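"""Minimum-strain inference from ratio fingerprints.

A sample's defined gene ratios are modeled as observed = C @ a where C is a
binary genes-x-k gene-content matrix and a is a strictly positive abundance
vector summing to 1 (one 16S copy per genome normalizes the total).  The
inferred strain count is the smallest k admitting a model whose worst
per-gene residual stays within epsilon.  This model-based minimum assumes
one 16S copy per genome, one copy of each gene per genome, and completeness
of the assay panel.

The search exploits the fact that, for fixed abundances, the optimal subset
assignment decouples per gene: each gene independently picks the nonempty
strain subset whose abundance sum is nearest its observed ratio.  Minimizing
the worst residual over the abundance simplex (grid + local refinement,
then an exact Chebyshev LP polish on the selected assignment) is therefore
equivalent to enumerating all gene-to-subset assignments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .fingerprint import RatioProfile

__all__ = [
    "InferenceConfig",
    "LevelSet",
    "StrainModel",
    "ratio_levels",
    "min_strain_lower_bound",
    "min_strain_decomposition",
    "colocalization_candidates",
    "chebyshev_fit",
]


@dataclass(frozen=True)
class InferenceConfig:
    tau_log10: float = 0.3  # level-merging tolerance, ~2-fold
    epsilon: float = 0.05  # absolute ratio residual tolerance
    k_max: int = 5
    r_min: float = 0.9  # co-variation threshold
    min_abundance: float = 1e-6

    def __post_init__(self) -> None:
        if self.tau_log10 <= 0:
            raise ValueError("tau_log10 must be positive")
        if not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass
class LevelSet:
    """Distinct abundance plateaus among a profile's defined ratios."""

    levels: list[tuple[float, list[str]]]  # (representative, member genes), desc

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def representatives(self) -> list[float]:
        return [v for v, _ in self.levels]


def ratio_levels(profile: RatioProfile, cfg: InferenceConfig | None = None) -> LevelSet:
    """Group defined ratios into levels spanning at most tau_log10 decades.

    Genes are scanned in descending ratio order; a gene joins the current
    level while log10(level max / ratio) <= tau, otherwise it opens a new
    level.  The representative is the geometric mean of member ratios.
    """
    cfg = cfg or InferenceConfig()
    items = sorted(profile.values.items(), key=lambda kv: (-kv[1], kv[0]))
    levels: list[tuple[float, list[str]]] = []
    out = []
    current: list[tuple[str, float]] = []
    for gene, value in items:
        if current and math.log10(current[0][1] / value) > cfg.tau_log10:
            out.append(current)
            current = []
        current.append((gene, value))
    if current:
        out.append(current)
    for group in out:
        rep = float(np.exp(np.mean([math.log(v) for _, v in group])))
        levels.append((rep, [g for g, _ in group]))
    return LevelSet(levels=levels)


def min_strain_lower_bound(levels: LevelSet) -> int:
    """k strains admit at most 2**k - 1 distinct positive subset sums, so L
    distinct levels force k >= ceil(log2(L + 1))."""
    L = len(levels)
    if L == 0:
        return 0
    return math.ceil(math.log2(L + 1))


@dataclass
class StrainModel:
    sample_id: str
    k: int | None  # None when no model found within k_max
    genes: list[str]
    content: np.ndarray  # genes x k binary
    abundances: np.ndarray  # k, descending, sums to 1
    residual: float
    lower_bound: int
    feasible: bool
    clipped_genes: list[str] = field(default_factory=list)
    note: str = ""

    def predicted(self) -> np.ndarray:
        return self.content @ self.abundances

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "k": self.k,
            "lower_bound": self.lower_bound,
            "feasible": self.feasible,
            "genes": self.genes,
            "content": self.content.astype(int).tolist(),
            "abundances": self.abundances.tolist(),
            "residual": self.residual,
            "note": self.note
            or "model-based minimum; assumes one 16S copy per genome, one copy "
            "per gene per genome, panel completeness",
        }


def _nonempty_subsets(k: int) -> np.ndarray:
    """All nonempty subsets of k strains as a (2^k - 1) x k binary array,
    ordered by popcount then lexicographically (prefers smaller subsets)."""
    masks = []
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            row = np.zeros(k)
            row[list(combo)] = 1.0
            masks.append(row)
    return np.array(masks)


def chebyshev_fit(
    content: np.ndarray, observed: np.ndarray, min_abundance: float = 1e-6
) -> tuple[np.ndarray, float] | None:
    """Exact min-max fit of abundances for a fixed binary content matrix.

    Solves min t s.t. |observed - C a| <= t, sum a = 1, a >= min_abundance
    as a linear program.  Returns (a, t) or None when infeasible.
    """
    g, k = content.shape
    # variables: a_1..a_k, t
    c = np.zeros(k + 1)
    c[-1] = 1.0
    A_ub = np.zeros((2 * g, k + 1))
    b_ub = np.zeros(2 * g)
    A_ub[:g, :k] = content
    A_ub[:g, -1] = -1.0
    b_ub[:g] = observed
    A_ub[g:, :k] = -content
    A_ub[g:, -1] = -1.0
    b_ub[g:] = -observed
    A_eq = np.zeros((1, k + 1))
    A_eq[0, :k] = 1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(min_abundance, 1.0)] * k + [(0, None)],
        method="highs",
    )
    if not res.success:
        return None
    return res.x[:k], float(res.x[-1])


def _simplex_grid(k: int, step: float, a_min: float) -> np.ndarray:
    """Interior points of the k-simplex on a regular grid."""
    n = round(1.0 / step)
    pts = []
    for combo in itertools.product(range(1, n), repeat=k - 1):
        rest = n - sum(combo)
        if rest < 1:
            continue
        pts.append([c * step for c in combo] + [rest * step])
    arr = np.array(pts) if pts else np.array([[1.0 / k] * k])
    return arr[(arr >= a_min).all(axis=1)]


def _residual_grid(points: np.ndarray, observed: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Worst per-gene deviation for each candidate abundance vector."""
    sums = points @ masks.T  # P x S
    # P x S x G deviations; keep memory modest by looping genes
    worst = np.zeros(points.shape[0])
    for v in observed:
        dev = np.abs(sums - v).min(axis=1)
        worst = np.maximum(worst, dev)
    return worst


def _assign_genes(a: np.ndarray, observed: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Per-gene optimal subset rows for fixed abundances (first best wins;
    mask ordering prefers smaller subsets, giving a deterministic, sparse
    content matrix)."""
    sums = masks @ a
    rows = []
    for v in observed:
        idx = int(np.argmin(np.abs(sums - v)))
        rows.append(masks[idx])
    return np.array(rows)


def _search_k(
    observed: np.ndarray, k: int, cfg: InferenceConfig
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Best model at fixed k: (content, abundances, residual), or None."""
    if k == 1:
        content = np.ones((len(observed), 1))
        resid = float(np.max(np.abs(observed - 1.0)))
        return content, np.array([1.0]), resid

    masks = _nonempty_subsets(k)
    step = {2: 0.002, 3: 0.01, 4: 0.02}.get(k, 0.04)
    pts = _simplex_grid(k, step, cfg.min_abundance)
    worst = _residual_grid(pts, observed, masks)
    best_a = pts[int(np.argmin(worst))]

    # local refinement around the best grid point
    for scale in (step / 5, step / 25):
        offsets = np.array(list(itertools.product((-2, -1, 0, 1, 2), repeat=k - 1)))
        cand = []
        for off in offsets:
            a = best_a.copy()
            a[:-1] = a[:-1] + off * scale
            a[-1] = 1.0 - a[:-1].sum()
            if (a >= cfg.min_abundance).all():
                cand.append(a)
        cand = np.array(cand)
        worst = _residual_grid(cand, observed, masks)
        best_a = cand[int(np.argmin(worst))]

    # exact polish: fix the assignment implied by best_a, solve the LP, and
    # iterate assignment/fit to a fixed point
    a = best_a
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(5):
        content = _assign_genes(a, observed, masks)
        fit = chebyshev_fit(content, observed, cfg.min_abundance)
        if fit is None:
            break
        a_new, resid = fit
        if best is None or resid < best[2] - 1e-12:
            best = (content, a_new, resid)
        if np.allclose(a_new, a, atol=1e-12):
            break
        a = a_new
    return best


def _canonicalize(
    content: np.ndarray, abundances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sort strains by descending abundance, ties by column pattern."""
    cols = [
        (-abundances[s], tuple(content[:, s].astype(int)), s)
        for s in range(content.shape[1])
    ]
    order = [s for *_, s in sorted(cols)]
    return content[:, order], abundances[order]


def min_strain_decomposition(
    profile: RatioProfile, cfg: InferenceConfig | None = None
) -> StrainModel:
    """Smallest-k binary-content x abundance model of a ratio profile.

    Defined genes must be explained within epsilon; censored genes only
    constrain the model from above (their content rows are zero, which
    always satisfies the below-detection bound).  Ratios above 1 are clipped
    to 1 + epsilon and flagged (possible within-OG cross-amplification).
    When no k <= k_max fits, the result reports k = None with the best
    residual found and a ">= k_max + 1" note.
    """
    cfg = cfg or InferenceConfig()
    genes = sorted(profile.values)
    if len(genes) == 0:
        raise ValueError(f"profile {profile.sample_id!r} has no defined ratios")
    if len(genes) > 12:
        raise ValueError("exact decomposition is desk-scale only (<= 12 defined genes)")
    observed = np.array([profile.values[g] for g in genes])
    clipped = [g for g, v in zip(genes, observed) if v > 1.0]
    observed = np.minimum(observed, 1.0 + cfg.epsilon)

    censored = sorted(profile.below_detection)
    lower = min_strain_lower_bound(ratio_levels(profile, cfg))

    best_overall: tuple[int, np.ndarray, np.ndarray, float] | None = None
    for k in range(1, cfg.k_max + 1):
        result = _search_k(observed, k, cfg)
        if result is None:
            continue
        content, a, resid = result
        if best_overall is None or resid < best_overall[3] - 1e-12:
            best_overall = (k, content, a, resid)
        if resid <= cfg.epsilon + 1e-12:
            content, a = _canonicalize(content, a)
            full = np.vstack([content, np.zeros((len(censored), k))])
            return StrainModel(
                sample_id=profile.sample_id,
                k=k,
                genes=genes + censored,
                content=full,
                abundances=a,
                residual=resid,
                lower_bound=lower,
                feasible=True,
                clipped_genes=clipped,
            )

    k_b, content, a, resid = best_overall
    content, a = _canonicalize(content, a)
    full = np.vstack([content, np.zeros((len(censored), k_b))])
    return StrainModel(
        sample_id=profile.sample_id,
        k=None,
        genes=genes + censored,
        content=full,
        abundances=a,
        residual=resid,
        lower_bound=lower,
        feasible=False,
        clipped_genes=clipped,
        note=f">= {cfg.k_max + 1} strains required (best residual {resid:.4f} at k={k_b})",
    )


def colocalization_candidates(
    profiles: list[RatioProfile], cfg: InferenceConfig | None = None
) -> list[list[str]]:
    """Gene groups that co-vary across samples at nearly equal magnitude.

    A pair qualifies when, over >= 3 shared defined samples, Pearson r of
    log10 ratios >= r_min and the median |delta log10 ratio| <= tau_log10.
    Qualifying pairs are merged by single linkage into maximal groups.
    """
    cfg = cfg or InferenceConfig()
    genes = sorted({g for p in profiles for g in p.values})
    series = {
        g: np.array(
            [math.log10(p.values[g]) if g in p.values else np.nan for p in profiles]
        )
        for g in genes
    }
    parent = {g: g for g in genes}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for ga, gb in itertools.combinations(genes, 2):
        xa, xb = series[ga], series[gb]
        mask = ~np.isnan(xa) & ~np.isnan(xb)
        if mask.sum() < 3:
            continue
        a, b = xa[mask], xb[mask]
        if a.std() == 0 or b.std() == 0:
            r = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        if r < cfg.r_min:
            continue
        if float(np.median(np.abs(a - b))) > cfg.tau_log10:
            continue
        ra, rb = find(ga), find(gb)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for g in genes:
        groups.setdefault(find(g), []).append(g)
    return sorted([sorted(v) for v in groups.values() if len(v) > 1])
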
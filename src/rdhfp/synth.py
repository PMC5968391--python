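"""Synthetic dechlorinating communities and qPCR plates with known truth.

Strains share one 16S copy per genome and differ in their binary gene
complements; electron-acceptor selection acts as a per-transfer
multiplicative fitness; plates carry seven-decade ten-fold standard series
and duplicate reactions at two dilutions, with Gaussian noise applied on the
Cq scale (instrument-like, lognormal in copy space).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fingerprint import SIXTEEN_S
from .qpcr import NO_AMPLIFICATION, SampleMeta

__all__ = [
    "DEFAULT_PANEL",
    "SyntheticStrain",
    "SyntheticTruth",
    "make_strains",
    "make_identifiable_strains",
    "simulate_selection",
    "simulate_plate",
    "truth_from_yaml",
]

#: gene panel mirroring a 15-assay rdhA suite plus functional biomarkers
DEFAULT_PANEL = [
    "KB1-1", "KB1-4", "KB1-5", "KB1-11", "KB1-12", "KB1-15", "KB1-16",
    "KB1-17", "KB1-18", "KB1-19", "KB1-23", "KB1-25", "KB1-6/bvcA",
    "KB1-14/vcrA", "KB1-27/tceA",
]

DEFAULT_CURVE = (-3.3219280948873623, 37.0)  # slope (100% efficiency), intercept


@dataclass
class SyntheticStrain:
    strain_id: str
    gene_content: dict[str, int]  # gene -> 0/1
    fitness: dict[str, float] = field(default_factory=dict)

    def content_vector(self, panel: list[str]) -> np.ndarray:
        return np.array([self.gene_content.get(g, 0) for g in panel], dtype=float)


def make_strains(
    n_strains: int,
    panel: list[str] | None = None,
    overlap: float = 0.3,
    seed: int = 0,
    max_attempts: int = 200,
) -> list[SyntheticStrain]:
    """Random strains: a core fraction of the panel present in every strain,
    remaining genes assigned independently; regenerates on content
    collisions and errors out when the panel cannot support unique strains."""
    panel = panel or DEFAULT_PANEL
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if not panel:
        raise ValueError("panel must be non-empty")
    if not (0 <= overlap <= 1):
        raise ValueError("overlap must lie in [0, 1]")
    n_core = round(overlap * len(panel))
    variable = panel[n_core:]
    if n_strains > 1 and 2 ** len(variable) < n_strains:
        raise ValueError(
            f"panel too small: {len(variable)} variable genes cannot distinguish "
            f"{n_strains} strains"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        contents = []
        for _ in range(n_strains):
            content = {g: 1 for g in panel[:n_core]}
            for g in variable:
                content[g] = int(rng.integers(0, 2))
            contents.append(content)
        keys = [tuple(sorted(c.items())) for c in contents]
        if len(set(keys)) == n_strains and all(sum(c.values()) > 0 for c in contents):
            return [
                SyntheticStrain(strain_id=f"strain_{i + 1}", gene_content=c)
                for i, c in enumerate(contents)
            ]
    raise ValueError("could not generate unique strain contents (overlap too high?)")


def make_identifiable_strains(
    n_strains: int, panel: list[str] | None = None, seed: int = 0
) -> list[SyntheticStrain]:
    """Strains guaranteed separable by ratio fingerprints: one signature gene
    unique to each strain, one core gene in all, remaining genes random."""
    panel = panel or DEFAULT_PANEL
    if len(panel) < n_strains + 1:
        raise ValueError("panel too small for signature construction")
    rng = np.random.default_rng(seed)
    strains = []
    core = panel[0]
    signatures = panel[1 : 1 + n_strains]
    rest = panel[1 + n_strains :]
    for i in range(n_strains):
        content = {core: 1}
        for j, sig in enumerate(signatures):
            content[sig] = int(i == j)
        for g in rest:
            content[g] = int(rng.integers(0, 2))
        strains.append(SyntheticStrain(strain_id=f"strain_{i + 1}", gene_content=content))
    return strains


def simulate_selection(
    strains: list[SyntheticStrain],
    acceptor_schedule: list[str],
    init_abundances: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Discrete serial transfers under per-acceptor multiplicative fitness.

    Returns the (len(schedule) + 1) x n_strains abundance series including
    the initial state; abundances renormalize each transfer.
    """
    n = len(strains)
    a = (
        np.full(n, 1.0 / n)
        if init_abundances is None
        else np.asarray(init_abundances, dtype=float)
    )
    if a.shape != (n,) or not np.isclose(a.sum(), 1.0):
        raise ValueError("init_abundances must be length n and sum to 1")
    series = [a.copy()]
    for acceptor in acceptor_schedule:
        w = np.array([s.fitness.get(acceptor, 0.0) for s in strains])
        nxt = a * w
        if nxt.sum() == 0:
            raise ValueError(f"all strains have zero fitness on {acceptor!r}")
        a = nxt / nxt.sum()
        series.append(a.copy())
    return np.array(series)


@dataclass
class SyntheticTruth:
    strains: list[SyntheticStrain]
    sample_abundances: dict[str, np.ndarray]  # sample -> abundance vector
    panel: list[str] = field(default_factory=lambda: list(DEFAULT_PANEL))
    total_16s_per_unit: float = 1e8
    curve_params: dict[str, tuple[float, float]] | None = None  # target -> (slope, intercept)
    cq_noise_sd: float = 0.0
    seed: int = 0
    meta: SampleMeta | None = None
    floor_copies_rxn: float = 10.0

    def __post_init__(self) -> None:
        for sid, a in self.sample_abundances.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (len(self.strains),) or not np.isclose(a.sum(), 1.0):
                raise ValueError(f"abundances for sample {sid!r} must sum to 1")
            self.sample_abundances[sid] = a
        if self.meta is None:
            self.meta = SampleMeta(
                sample_id="template",
                volume_filtered=10.0,
                elution_volume_ul=50.0,
                template_volume_ul=2.0,
                matrix="culture_per_mL",
            )

    def targets(self) -> list[str]:
        return [SIXTEEN_S] + list(self.panel)

    def curve_for(self, target: str) -> tuple[float, float]:
        if self.curve_params and target in self.curve_params:
            return self.curve_params[target]
        return DEFAULT_CURVE

    def expected_ratios(self, sample_id: str) -> dict[str, float]:
        a = self.sample_abundances[sample_id]
        content = np.array([s.content_vector(self.panel) for s in self.strains])
        ratios = content.T @ a
        return dict(zip(self.panel, ratios))

    def copies_per_unit(self, sample_id: str, target: str) -> float:
        if target == SIXTEEN_S:
            return self.total_16s_per_unit
        return self.total_16s_per_unit * self.expected_ratios(sample_id)[target]


def simulate_plate(
    truth: SyntheticTruth, sample_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit a plate table, sample metadata table and a truth record.

    Per target: a 7-point ten-fold standard series (10^1..10^7 copies per
    reaction) plus, for each sample, duplicate reactions at dilution 1 and
    10.  Reactions whose per-reaction copies fall below the floor are
    emitted as no-amplification.
    """
    sample_ids = sample_ids or sorted(truth.sample_abundances)
    rng = np.random.default_rng(truth.seed)
    meta = truth.meta
    rows = []
    well = 0

    def next_well() -> str:
        nonlocal well
        well += 1
        return f"W{well:04d}"

    for target in truth.targets():
        slope, intercept = truth.curve_for(target)
        for exp in range(1, 8):
            copies = 10.0 ** exp
            cq = intercept + slope * exp + rng.normal(0.0, truth.cq_noise_sd)
            rows.append(
                {
                    "well": next_well(),
                    "sample_id": "",
                    "target": target,
                    "cq": round(cq, 4),
                    "dilution_factor": 1.0,
                    "is_standard": True,
                    "standard_copies": copies,
                }
            )
        for sid in sample_ids:
            per_unit = truth.copies_per_unit(sid, target)
            for dilution in (1.0, 10.0):
                for _ in range(2):  # duplicates
                    copies_rxn = (
                        per_unit
                        * meta.volume_filtered
                        * (meta.template_volume_ul / meta.elution_volume_ul)
                        / dilution
                    )
                    if copies_rxn < truth.floor_copies_rxn:
                        cq_out: float | str = NO_AMPLIFICATION
                    else:
                        cq = (
                            intercept
                            + slope * np.log10(copies_rxn)
                            + rng.normal(0.0, truth.cq_noise_sd)
                        )
                        cq_out = round(float(cq), 6)
                    rows.append(
                        {
                            "well": next_well(),
                            "sample_id": sid,
                            "target": target,
                            "cq": cq_out,
                            "dilution_factor": dilution,
                            "is_standard": False,
                            "standard_copies": "",
                        }
                    )

    plate = pd.DataFrame(rows)
    meta_rows = [
        {
            "sample_id": sid,
            "volume_filtered": meta.volume_filtered,
            "elution_volume_ul": meta.elution_volume_ul,
            "template_volume_ul": meta.template_volume_ul,
            "matrix": meta.matrix,
        }
        for sid in sample_ids
    ]
    meta_df = pd.DataFrame(meta_rows)
    truth_record = {
        "seed": truth.seed,
        "cq_noise_sd": truth.cq_noise_sd,
        "total_16s_per_unit": truth.total_16s_per_unit,
        "panel": truth.panel,
        "strains": [
            {"strain_id": s.strain_id, "gene_content": s.gene_content}
            for s in truth.strains
        ],
        "sample_abundances": {
            sid: truth.sample_abundances[sid].tolist() for sid in sample_ids
        },
        "expected_ratios": {sid: truth.expected_ratios(sid) for sid in sample_ids},
    }
    return plate, meta_df, truth_record


def truth_from_yaml(path) -> SyntheticTruth:
    """Build a truth object from a config YAML (panel, strains, fitness,
    abundances or schedule, noise, volumes, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    panel = cfg.get("panel", DEFAULT_PANEL)
    strains = [
        SyntheticStrain(
            strain_id=s["strain_id"],
            gene_content={g: int(v) for g, v in s["gene_content"].items()},
            fitness={k: float(v) for k, v in s.get("fitness", {}).items()},
        )
        for s in cfg["strains"]
    ]
    if "sample_abundances" in cfg:
        abundances = {
            sid: np.asarray(a, dtype=float)
            for sid, a in cfg["sample_abundances"].items()
        }
    else:
        schedule = cfg["acceptor_schedule"]
        series = simulate_selection(strains, schedule)
        abundances = {f"transfer_{t}": series[t] for t in range(len(series))}
    volumes = cfg.get("volumes", {})
    meta = SampleMeta(
        sample_id="template",
        volume_filtered=float(volumes.get("volume_filtered", 10.0)),
        elution_volume_ul=float(volumes.get("elution_volume_ul", 50.0)),
        template_volume_ul=float(volumes.get("template_volume_ul", 2.0)),
        matrix=volumes.get("matrix", "culture_per_mL"),
    )
    return SyntheticTruth(
        strains=strains,
        sample_abundances=abundances,
        panel=panel,
        total_16s_per_unit=float(cfg.get("total_16s_per_unit", 1e8)),
        cq_noise_sd=float(cfg.get("cq_noise_sd", 0.0)),
        seed=int(cfg.get("seed", 0)),
        meta=meta,
        floor_copies_rxn=float(cfg.get("floor_copies_rxn", 10.0)),
    )


def write_outputs(
    plate: pd.DataFrame, meta_df: pd.DataFrame, truth_record: dict, out_dir
) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plate.to_csv(out / "plate.csv", index=False)
    meta_df.to_csv(out / "meta.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_record, fh, indent=2, sort_keys=True)
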
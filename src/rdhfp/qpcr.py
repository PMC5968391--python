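"""qPCR standard curves, absolute quantification, replicate QC and MDLs.

Quantification inverts the fitted log-linear calibration in base 10:
copies = dilution_factor * 10**((cq - intercept) / slope).  "No
amplification" is propagated as a censored value, never as zero, so that
downstream ratio fingerprints can distinguish "absent" from "below limit".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NO_AMPLIFICATION",
    "StandardCurve",
    "Reaction",
    "SampleMeta",
    "Measurement",
    "fit_standard_curve",
    "quantify_reaction",
    "merge_replicates",
    "to_concentration",
    "compute_mdl",
    "read_plate",
    "read_sample_meta",
    "quantify_plate",
    "measurements_to_frame",
]

NO_AMPLIFICATION = "no-amplification"

#: default per-reaction quantification floor (copies per reaction)
DEFAULT_FLOOR = 10.0


@dataclass(frozen=True)
class StandardCurve:
    target: str
    slope: float  # Cq per log10(copies); negative for a working assay
    intercept: float  # Cq at 1 copy
    r2: float
    quant_range: tuple[float, float]  # (min, max) standard copies per reaction

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0

    def forward_cq(self, copies: float) -> float:
        """Noise-free Cq predicted for a given per-reaction copy number."""
        return self.intercept + self.slope * math.log10(copies)


@dataclass(frozen=True)
class Reaction:
    well: str
    target: str
    cq: float | str  # numeric, or NO_AMPLIFICATION
    dilution_factor: float = 1.0
    is_standard: bool = False
    standard_copies: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.is_standard and self.standard_copies is None:
            raise ValueError(f"standard reaction {self.well} lacks standard_copies")
        if self.amplified and float(self.cq) <= 0:
            raise ValueError(f"reaction {self.well}: Cq must be positive")

    @property
    def amplified(self) -> bool:
        return not (
            self.cq is None
            or (isinstance(self.cq, str) and self.cq == NO_AMPLIFICATION)
            or (isinstance(self.cq, float) and math.isnan(self.cq))
        )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    volume_filtered: float  # in the unit implied by `matrix`
    elution_volume_ul: float
    template_volume_ul: float = 2.0
    matrix: str = "culture_per_mL"  # or "groundwater_per_L"

    def __post_init__(self) -> None:
        if self.matrix not in ("culture_per_mL", "groundwater_per_L"):
            raise ValueError(f"unknown matrix {self.matrix!r}")
        for name in ("volume_filtered", "elution_volume_ul", "template_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def unit(self) -> str:
        return "copies/mL" if self.matrix == "culture_per_mL" else "copies/L"


@dataclass
class Measurement:
    sample_id: str
    target: str
    copies_per_unit: float  # equals mdl_per_unit when censored
    unit: str
    censored: bool
    mdl_per_unit: float
    qc_flags: set[str] = field(default_factory=set)

    def report_value(self) -> str:
        if self.censored:
            return f"<{self.mdl_per_unit:g}"
        return f"{self.copies_per_unit:g}"


def fit_standard_curve(standards: list[Reaction]) -> StandardCurve:
    """Ordinary least squares of Cq on log10(standard copies)."""
    pts = [
        (float(r.standard_copies), float(r.cq))
        for r in standards
        if r.is_standard and r.amplified
    ]
    concs = {c for c, _ in pts}
    if len(concs) < 3:
        raise ValueError(
            f"need >= 3 distinct standard concentrations, got {len(concs)}"
        )
    x = np.log10([c for c, _ in pts])
    y = np.array([cq for _, cq in pts])
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("positive standard-curve slope: calibrator order suspect")
    targets = {r.target for r in standards}
    target = targets.pop() if len(targets) == 1 else "mixed"
    return StandardCurve(
        target=target,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        quant_range=(min(concs), max(concs)),
    )


def quantify_reaction(
    cq: float | str, curve: StandardCurve, dilution_factor: float = 1.0
) -> tuple[float | None, set[str]]:
    """Convert one Cq to dilution-corrected copies per reaction.

    Returns (copies, qc_flags); copies is None for a censored (no
    amplification) reaction.  Range flags compare the in-reaction copy
    number against the span of the calibrators.
    """
    flags: set[str] = set()
    if isinstance(cq, str):
        if cq == NO_AMPLIFICATION:
            return None, flags
        cq = float(cq)
    if cq is None or (isinstance(cq, float) and math.isnan(cq)):
        return None, flags
    in_reaction = 10 ** ((cq - curve.intercept) / curve.slope)
    lo, hi = curve.quant_range
    if in_reaction < lo:
        flags.add("below_range")
    elif in_reaction > hi:
        flags.add("above_range")
    return dilution_factor * in_reaction, flags


def _geomean(values: list[float]) -> float:
    return float(np.exp(np.mean(np.log(values))))


def merge_replicates(
    reactions: list[Reaction],
    curve: StandardCurve,
    agreement_fold: float = 2.0,
) -> tuple[float | None, set[str]]:
    """Merge duplicate/dilution reactions of one sample+target.

    Estimates are dilution-corrected and combined with a geometric mean.
    When the undiluted and diluted estimates disagree by more than
    ``agreement_fold``, the diluted estimate is kept (inhibition assumption)
    and ``dilution_disagreement`` is flagged.  Returns (copies per reaction,
    flags); copies is None when every reaction is censored.
    """
    flags: set[str] = set()
    by_dilution: dict[float, list[float]] = {}
    for r in sorted(reactions, key=lambda r: (r.dilution_factor, r.well)):
        copies, f = quantify_reaction(r.cq, curve, r.dilution_factor)
        flags |= f
        if copies is not None:
            by_dilution.setdefault(r.dilution_factor, []).append(copies)
    if not by_dilution:
        return None, flags
    per_dilution = {d: _geomean(v) for d, v in by_dilution.items()}
    if len(per_dilution) > 1:
        lowest = per_dilution[min(per_dilution)]
        highest = per_dilution[max(per_dilution)]
        ratio = max(lowest, highest) / min(lowest, highest)
        if ratio > agreement_fold:
            flags.add("dilution_disagreement")
            return highest, flags  # trust the diluted reaction
    return _geomean(list(per_dilution.values())), flags


def to_concentration(copies_rxn: float, meta: SampleMeta) -> float:
    """Scale per-reaction copies to the sample matrix unit."""
    return (
        copies_rxn
        * (meta.elution_volume_ul / meta.template_volume_ul)
        / meta.volume_filtered
    )


def compute_mdl(
    curve: StandardCurve,
    meta: SampleMeta,
    lowest_quantifiable_copies_rxn: float = DEFAULT_FLOOR,
) -> float:
    """Method detection limit in the sample's matrix unit."""
    return to_concentration(lowest_quantifiable_copies_rxn, meta)


# ---------------------------------------------------------------------------
# plate-level pipeline


def read_plate(path) -> list[Reaction]:
    """Plate CSV: well,sample_id,target,cq,dilution_factor,is_standard,standard_copies."""
    df = pd.read_csv(path)
    reactions = []
    for _, row in df.iterrows():
        raw_cq = row["cq"]
        if pd.isna(raw_cq) or str(raw_cq).strip() in ("", NO_AMPLIFICATION, "NA"):
            cq: float | str = NO_AMPLIFICATION
        else:
            cq = float(raw_cq)
        std_copies = row.get("standard_copies")
        reactions.append(
            Reaction(
                well=str(row["well"]),
                sample_id=None if pd.isna(row.get("sample_id")) else str(row["sample_id"]),
                target=str(row["target"]),
                cq=cq,
                dilution_factor=float(row.get("dilution_factor", 1.0)),
                is_standard=bool(row.get("is_standard", False)),
                standard_copies=None if pd.isna(std_copies) else float(std_copies),
            )
        )
    return reactions


def read_sample_meta(path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            volume_filtered=float(row["volume_filtered"]),
            elution_volume_ul=float(row["elution_volume_ul"]),
            template_volume_ul=float(row.get("template_volume_ul", 2.0)),
            matrix=str(row["matrix"]),
        )
        out[meta.sample_id] = meta
    return out


def quantify_plate(
    reactions: list[Reaction],
    meta: dict[str, SampleMeta],
    agreement_fold: float = 2.0,
    floor_copies_rxn: float = DEFAULT_FLOOR,
) -> list[Measurement]:
    """Full plate workflow: fit curves per target, merge replicates, scale to
    concentrations and censor at the MDL."""
    standards: dict[str, list[Reaction]] = {}
    samples: dict[tuple[str, str], list[Reaction]] = {}
    for r in reactions:
        if r.is_standard:
            standards.setdefault(r.target, []).append(r)
        else:
            if r.sample_id is None:
                raise ValueError(f"non-standard reaction {r.well} lacks sample_id")
            samples.setdefault((r.sample_id, r.target), []).append(r)

    curves = {t: fit_standard_curve(rs) for t, rs in standards.items()}
    measurements = []
    for (sample_id, target), rs in sorted(samples.items()):
        if target not in curves:
            raise ValueError(f"no standard curve for target {target!r}")
        if sample_id not in meta:
            raise ValueError(f"no sample metadata for {sample_id!r}")
        m = meta[sample_id]
        curve = curves[target]
        copies_rxn, flags = merge_replicates(rs, curve, agreement_fold)
        mdl = compute_mdl(curve, m, floor_copies_rxn)
        if copies_rxn is None:
            measurements.append(
                Measurement(sample_id, target, mdl, m.unit, True, mdl, flags)
            )
            continue
        conc = to_concentration(copies_rxn, m)
        censored = conc < mdl
        measurements.append(
            Measurement(
                sample_id,
                target,
                mdl if censored else conc,
                m.unit,
                censored,
                mdl,
                flags,
            )
        )
    return measurements


def measurements_to_frame(measurements: list[Measurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in measurements],
            "target": [m.target for m in measurements],
            "copies_per_unit": [
                float("nan") if m.censored else m.copies_per_unit for m in measurements
            ],
            "unit": [m.unit for m in measurements],
            "censored": [m.censored for m in measurements],
            "mdl": [m.mdl_per_unit for m in measurements],
            "qc_flags": [";".join(sorted(m.qc_flags)) for m in measurements],
        }
    )
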
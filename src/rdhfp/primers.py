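"""In-silico qPCR primer specificity screening.

Matching is ungapped: a primer is slid over both strands of the template and
mismatches are counted per offset (Hamming).  A degenerate base matches when
the IUPAC expansions of primer and template base intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .seqalign import NT_EXPANSION, Molecule, SequenceRecord, SequenceSet

__all__ = ["Strand", "PrimerPair", "MatchResult", "reverse_complement",
           "best_primer_match", "screen_primer_pair", "read_primer_table",
           "screen_to_frame"]

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class PrimerPair:
    """A named qPCR primer pair; both primers are written 5'->3'."""

    name: str
    fwd: str
    rev: str
    annealing_temp: float = 60.0
    target_gene: str = ""

    def __post_init__(self) -> None:
        for label, p in (("fwd", self.fwd), ("rev", self.rev)):
            p = p.upper()
            object.__setattr__(self, label, p)
            if not (10 <= len(p) <= 40):
                raise ValueError(
                    f"primer {self.name}/{label} length {len(p)} outside [10, 40]"
                )
            bad = [c for c in p if c not in NT_EXPANSION]
            if bad:
                raise ValueError(f"primer {self.name}/{label}: invalid base {bad[0]!r}")


@dataclass(frozen=True)
class MatchResult:
    sequence_id: str
    fwd_mismatches: int
    rev_mismatches: int
    fwd_pos: int
    rev_pos: int
    amplicon_length: int | None
    orientation_ok: bool
    fwd_three_prime_mismatch_offset: int | None = None
    rev_three_prime_mismatch_offset: int | None = None


def _mismatches(primer: str, window: str) -> int:
    count = 0
    for p, t in zip(primer, window):
        if not (NT_EXPANSION[p] & NT_EXPANSION[t]):
            count += 1
    return count


def _three_prime_offset(primer: str, window: str) -> int | None:
    """Distance of the 3'-most mismatch from the primer 3' end (0 = terminal)."""
    for off in range(len(primer)):
        p = primer[len(primer) - 1 - off]
        t = window[len(primer) - 1 - off]
        if not (NT_EXPANSION[p] & NT_EXPANSION[t]):
            return off
    return None


def _best_on_strand(primer: str, template: str) -> tuple[int, int]:
    best_mm, best_pos = len(primer) + 1, -1
    L = len(primer)
    for off in range(len(template) - L + 1):
        mm = _mismatches(primer, template[off : off + L])
        if mm < best_mm:
            best_mm, best_pos = mm, off
            if mm == 0:
                break
    return best_mm, best_pos


def best_primer_match(
    primer: str, template: SequenceRecord
) -> tuple[int, int, Strand]:
    """Minimum Hamming mismatches over all ungapped offsets on both strands.

    Ties resolve to the smallest offset, forward strand first.  The offset
    is reported on the plus strand of the template as given.
    """
    if template.molecule is not Molecule.NT:
        raise ValueError("primer matching requires a nucleotide template")
    primer = primer.upper()
    if len(template.residues) < len(primer):
        raise ValueError(
            f"template {template.id!r} shorter than primer ({len(template)} < {len(primer)})"
        )
    seq = template.residues
    fwd_mm, fwd_pos = _best_on_strand(primer, seq)
    # minus strand: the primer's reverse complement read on the plus strand
    rc = reverse_complement(primer)
    rev_mm, rev_pos = _best_on_strand(rc, seq)
    if fwd_mm <= rev_mm:
        return fwd_mm, fwd_pos, Strand.PLUS
    return rev_mm, rev_pos, Strand.MINUS


def screen_primer_pair(pair: PrimerPair, seqs: SequenceSet) -> list[MatchResult]:
    """Screen a primer pair against every sequence.

    The forward primer is matched on the plus strand and the reverse primer
    on the minus strand (its reverse complement on the plus strand).  An
    amplicon is called when the forward site lies upstream of the reverse
    site; its length spans the forward 5' to the reverse 5' coordinate.
    """
    out: list[MatchResult] = []
    for rec in seqs:
        seq = rec.residues
        if len(seq) < max(len(pair.fwd), len(pair.rev)):
            out.append(MatchResult(rec.id, -1, -1, -1, -1, None, False))
            continue
        fwd_mm, fwd_pos = _best_on_strand(pair.fwd, seq)
        rc = reverse_complement(pair.rev)
        rev_mm, rev_pos = _best_on_strand(rc, seq)
        rev_end = rev_pos + len(pair.rev) - 1  # reverse primer 5' on plus strand
        ok = fwd_pos >= 0 and rev_pos >= 0 and fwd_pos + len(pair.fwd) <= rev_pos
        amplicon = rev_end - fwd_pos + 1 if ok else None
        fwd_win = seq[fwd_pos : fwd_pos + len(pair.fwd)]
        rev_win_rc = reverse_complement(seq[rev_pos : rev_pos + len(pair.rev)])
        out.append(
            MatchResult(
                sequence_id=rec.id,
                fwd_mismatches=fwd_mm,
                rev_mismatches=rev_mm,
                fwd_pos=fwd_pos,
                rev_pos=rev_pos,
                amplicon_length=amplicon,
                orientation_ok=ok,
                fwd_three_prime_mismatch_offset=_three_prime_offset(pair.fwd, fwd_win),
                rev_three_prime_mismatch_offset=_three_prime_offset(pair.rev, rev_win_rc),
            )
        )
    return out


def read_primer_table(path) -> list[PrimerPair]:
    """TSV columns: name, fwd, rev, annealing_temp_C, target_gene[, amplicon_len]."""
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(
            PrimerPair(
                name=str(row["name"]),
                fwd=str(row["fwd"]),
                rev=str(row["rev"]),
                annealing_temp=float(row.get("annealing_temp_C", 60.0)),
                target_gene=str(row.get("target_gene", "")),
            )
        )
    return pairs


def screen_to_frame(pair: PrimerPair, results: list[MatchResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "primer_pair": pair.name,
                "sequence_id": r.sequence_id,
                "fwd_mismatches": r.fwd_mismatches,
                "rev_mismatches": r.rev_mismatches,
                "fwd_pos": r.fwd_pos,
                "rev_pos": r.rev_pos,
                "amplicon_length": r.amplicon_length,
                "orientation_ok": r.orientation_ok,
                "fwd_3p_mismatch_offset": r.fwd_three_prime_mismatch_offset,
                "rev_3p_mismatch_offset": r.rev_three_prime_mismatch_offset,
            }
        )
    return pd.DataFrame(rows)
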
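"""Sequence records, FASTA I/O and pairwise global alignment.

Percent identity (PID) between two sequences is computed from a single
optimal global alignment under affine gap penalties as

    pid = identical columns / columns where both rows carry a residue

so end overhangs and internal gap columns never inflate nor deflate the
denominator.  Degenerate nucleotide codes never count as identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "Molecule",
    "Scheme",
    "SequenceRecord",
    "SequenceSet",
    "AlignParams",
    "AlignmentResult",
    "read_fasta",
    "write_fasta",
    "filter_full_length",
    "global_align",
    "percent_identity",
]


class Molecule(str, Enum):
    AA = "aa"
    NT = "nt"


class Scheme(str, Enum):
    IDENTITY_NT = "identity_nt"
    IUB_NT = "iub_nt"
    PROTEIN_DEFAULT = "protein_default"


#: IUPAC degenerate nucleotide codes expanded to the canonical bases.
NT_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
NT_ALPHABET = frozenset(NT_EXPANSION)

GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """One named amino-acid or nucleotide sequence."""

    id: str
    molecule: Molecule
    residues: str
    source_strain: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        alphabet = NT_ALPHABET if self.molecule is Molecule.NT else AA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in alphabet:
                raise ValueError(
                    f"sequence {self.id!r}: invalid {self.molecule.value} "
                    f"residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


class SequenceSet:
    """Ordered collection of records with unique ids and one molecule type."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        seen: dict[str, SequenceRecord] = {}
        molecule = None
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen[rec.id] = rec
            if molecule is None:
                molecule = rec.molecule
            elif rec.molecule is not molecule:
                raise ValueError(
                    f"mixed molecule types in set ({rec.id!r} is {rec.molecule.value})"
                )
        self._by_id = seen
        self.molecule = molecule

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: str | int) -> SequenceRecord:
        if isinstance(key, int):
            return self.records[key]
        return self._by_id[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def read_fasta(path, molecule: Molecule | str, source_strain: str = "") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace becomes the record id.
    Duplicate ids, empty files and out-of-alphabet residues are hard errors.
    """
    molecule = Molecule(molecule)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=entry.id,
                molecule=molecule,
                residues=str(entry.seq),
                source_strain=source_strain,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping residues at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def filter_full_length(
    seqs: SequenceSet, min_nt: int = 850
) -> tuple[SequenceSet, SequenceSet]:
    """Split a set into (kept, excluded) at a minimum length, order preserved.

    Records strictly shorter than ``min_nt`` are excluded.
    """
    kept = [r for r in seqs if r.length >= min_nt]
    excluded = [r for r in seqs if r.length < min_nt]
    return SequenceSet(kept), SequenceSet(excluded)


@dataclass(frozen=True)
class AlignParams:
    """Affine gap penalties and substitution scheme for pairwise alignment.

    A gap run of length L costs ``gap_open + L * gap_extend``.
    """

    gap_open: float = 10.0
    gap_extend: float = 0.1
    substitution_scheme: Scheme = Scheme.PROTEIN_DEFAULT

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _nt_score(a: str, b: str, match: float, partial: float) -> float:
    ea, eb = NT_EXPANSION[a], NT_EXPANSION[b]
    if a == b and len(ea) == 1:
        return match
    if frozenset((a, b)) in _TRANSITIONS:
        return partial
    if ea & eb:
        # degenerate overlap: scored as a down-weighted match, never identity
        return partial
    return 0.0


def _score_fn(scheme: Scheme):
    if scheme is Scheme.IDENTITY_NT:
        return lambda a, b: _nt_score(a, b, 1.0, 0.0)
    if scheme is Scheme.IUB_NT:
        return lambda a, b: _nt_score(a, b, 1.9, 0.95)

    def protein(a: str, b: str) -> float:
        a = a if a in _BLOSUM62.alphabet else "X"
        b = b if b in _BLOSUM62.alphabet else "X"
        return float(_BLOSUM62[a, b])

    return protein


def default_params(molecule: Molecule) -> AlignParams:
    """Conventional parameters: IUB-style scoring for nt, BLOSUM62 for aa."""
    scheme = Scheme.IUB_NT if molecule is Molecule.NT else Scheme.PROTEIN_DEFAULT
    return AlignParams(substitution_scheme=scheme)


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    aligned_columns: int
    all_gap_overlap: bool = False

    @property
    def pid(self) -> float:
        return percent_identity(self)


def _column_stats(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    matches = 0
    cols = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != GAP and y != GAP:
            cols += 1
            if x == y:
                matches += 1
    return matches, cols


# traceback state codes
_M, _X, _Y = 0, 1, 2


def global_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> AlignmentResult:
    """Optimal global alignment of two records (Gotoh, affine gaps).

    Deterministic traceback: on score ties prefer the diagonal move, then a
    gap in the second sequence ("up"), then a gap in the first ("left").
    """
    if a.molecule is not b.molecule:
        raise ValueError("cannot align records of different molecule types")
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequence")
    if params is None:
        params = default_params(a.molecule)

    score = _score_fn(params.substitution_scheme)
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    go = params.gap_open + params.gap_extend  # first residue of a gap run
    ge = params.gap_extend
    NEG = float("-inf")

    # DP matrices: M ends in a residue column, X in a gap in b (consumes a),
    # Y in a gap in a (consumes b).
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr_m = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(params.gap_open + i * ge)
        ptr_x[i][0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0][j] = -(params.gap_open + j * ge)
        ptr_y[0][j] = _Y if j > 1 else _M

    for i in range(1, n + 1):
        row_m, row_x, row_y = M[i], X[i], Y[i]
        pm, px, py = ptr_m[i], ptr_x[i], ptr_y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        ca = sa[i - 1]
        for j in range(1, m + 1):
            s = score(ca, sb[j - 1])
            # diagonal move into M
            best, arg = prev_m[j - 1], _M
            if prev_x[j - 1] > best:
                best, arg = prev_x[j - 1], _X
            if prev_y[j - 1] > best:
                best, arg = prev_y[j - 1], _Y
            row_m[j] = best + s
            pm[j] = arg
            # up move into X (gap in b)
            best, arg = prev_m[j] - go, _M
            if prev_x[j] - ge > best:
                best, arg = prev_x[j] - ge, _X
            if prev_y[j] - go > best:
                best, arg = prev_y[j] - go, _Y
            row_x[j] = best
            px[j] = arg
            # left move into Y (gap in a)
            best, arg = row_m[j - 1] - go, _M
            if row_x[j - 1] - go > best:
                best, arg = row_x[j - 1] - go, _X
            if row_y[j - 1] - ge > best:
                best, arg = row_y[j - 1] - ge, _Y
            row_y[j] = best
            py[j] = arg

    end_scores = (M[n][m], X[n][m], Y[n][m])
    state = max((_M, _X, _Y), key=lambda s: (end_scores[s], -s))
    total = end_scores[state]

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            prev = ptr_m[i][j]
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif state == _X:
            prev = ptr_x[i][j]
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            prev = ptr_y[i][j]
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
        state = prev
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))

    matches, cols = _column_stats(aligned_a, aligned_b)
    return AlignmentResult(
        id_a=a.id,
        id_b=b.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=total,
        matches=matches,
        aligned_columns=cols,
        all_gap_overlap=(cols == 0),
    )


def percent_identity(r: AlignmentResult) -> float:
    """matches / aligned_columns in [0, 1]; 0 with a warning if no overlap."""
    if r.aligned_columns == 0:
        warnings.warn(
            f"alignment {r.id_a}/{r.id_b} has no residue-residue columns; PID set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return r.matches / r.aligned_columns
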
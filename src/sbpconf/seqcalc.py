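"""Pairwise sequence utilities: global alignment/identity, molecular weight, ε280.

Alignment is Needleman–Wunsch with affine gaps (BLOSUM62, open 10, extend 0.5),
delegated to :class:`Bio.Align.PairwiseAligner`. Percent identity is computed
over columns where both positions are residues — the only convention that
yields a single number for sequences of unequal length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import FormatError

STANDARD_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_ALPHABET = STANDARD_ALPHABET | {"X"}

#: Trp/Tyr/cystine molar extinction coefficients at 280 nm (M⁻¹ cm⁻¹).
EPS_TRP, EPS_TYR, EPS_CYSTINE = 5500.0, 1490.0, 125.0

WATER_MASS = 18.02


@dataclass
class AlignmentResult:
    """A pairwise global alignment with gap characters and its summary scores."""

    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        return percent_identity(self)


def _validate(seq: str, label: str, allow_x: bool = True) -> str:
    seq = seq.upper()
    alphabet = EXTENDED_ALPHABET if allow_x else STANDARD_ALPHABET
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise FormatError(f"illegal character {ch!r} at position {pos} of {label}")
    if not seq:
        raise FormatError(f"{label} must be non-empty")
    return seq


def global_align(seq_a: str, seq_b: str, matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> AlignmentResult:
    """Globally align two protein sequences (affine-gap Needleman–Wunsch)."""
    seq_a = _validate(seq_a, "sequence a")
    seq_b = _validate(seq_b, "sequence b")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    return AlignmentResult(aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=aln.score)


def percent_identity(aln: AlignmentResult) -> float:
    """Identity over both-residue columns, as a percentage rounded to 1 decimal."""
    both = ident = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                ident += 1
    if both == 0:
        raise FormatError("alignment has no columns where both positions are residues")
    return round(100.0 * ident / both, 1)


def molecular_weight(seq: str) -> float:
    """Average molecular weight (g/mol) of the peptide, including one water."""
    seq = _validate(seq, "sequence", allow_x=False)
    return float(ProteinAnalysis(seq).molecular_weight())


def extinction_coefficient(seq: str, cystine_assumption: str = "reduced") -> float:
    """ε280 (M⁻¹ cm⁻¹): 5500·nW + 1490·nY, plus 125 per cystine pair if oxidized."""
    seq = _validate(seq, "sequence", allow_x=False)
    if cystine_assumption not in ("reduced", "oxidized"):
        raise ValueError("cystine_assumption must be 'reduced' or 'oxidized'")
    eps = EPS_TRP * seq.count("W") + EPS_TYR * seq.count("Y")
    if cystine_assumption == "oxidized":
        eps += EPS_CYSTINE * (seq.count("C") // 2)
    return eps


def e0p1_percent(seq: str, cystine_assumption: str = "reduced") -> float:
    """E0.1% at 280 nm (dL·g⁻¹·cm⁻¹): ε280 / MW × 10, as used for labeling ratios."""
    return extinction_coefficient(seq, cystine_assumption) / molecular_weight(seq) * 10.0
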
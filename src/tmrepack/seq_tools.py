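"""Global pairwise protein alignment with identity/similarity percentages.

Convention (declared in all outputs): Needleman–Wunsch global alignment with
affine gaps (BLOSUM62, gap open 10, gap extend 0.5, a length-L gap costing
``open + extend × (L − 1)``); identity = identical aligned pairs over
both-non-gap columns; similarity = columns with a positive substitution score
over both-non-gap columns. Report values are rounded half-up to integers; raw
floats are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: bundled reference sequences (FASTA, plain text)
DATA_PACKAGE = "tmrepack.data"


def validate_protein(seq: str, label: str = "sequence") -> str:
    seq = seq.strip().upper()
    for i, ch in enumerate(seq):
        if ch not in VALID_AA:
            raise ValueError(
                f"{label}: non-amino-acid character {ch!r} at position {i + 1}"
            )
    return seq


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    percent_similarity: float

    @property
    def identity_rounded(self) -> int:
        return round_half_up(self.percent_identity)

    @property
    def similarity_rounded(self) -> int:
        return round_half_up(self.percent_similarity)


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def identity_similarity(
    aligned_a: str,
    aligned_b: str,
    matrix: str = "BLOSUM62",
) -> tuple[float, float]:
    """Percent identity and similarity over both-non-gap aligned columns.

    Returns ``(nan, nan)`` when no column has residues on both sides.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    sub = substitution_matrices.load(matrix)
    n_cols = n_ident = n_sim = 0
    for a, b in zip(aligned_a, aligned_b):
        if a == "-" or b == "-":
            continue
        n_cols += 1
        if a == b:
            n_ident += 1
        if sub[a, b] > 0:
            n_sim += 1
    if n_cols == 0:
        return float("nan"), float("nan")
    return 100.0 * n_ident / n_cols, 100.0 * n_sim / n_cols


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    The first optimal alignment of the (deterministic) traceback enumeration
    is reported.
    """
    seq_a = validate_protein(seq_a, "sequence A")
    seq_b = validate_protein(seq_b, "sequence B")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    ident, sim = identity_similarity(aligned_a, aligned_b, matrix)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        percent_identity=ident,
        percent_similarity=sim,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file → {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_reference_sequence(name: str) -> str:
    """Load a bundled reference FASTA (e.g. ``abcb1_human`` or ``abcb1a_mouse``)."""
    with resources.files(DATA_PACKAGE).joinpath(f"{name}.fasta").open() as fh:
        recs = list(SeqIO.parse(fh, "fasta"))
    if not recs:
        raise FileNotFoundError(f"no records in bundled FASTA {name!r}")
    return str(recs[0].seq)
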
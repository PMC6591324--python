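"""Pairwise alignment primitives.

Global (Needleman-Wunsch) and local (Smith-Waterman) protein/DNA alignment
with affine gap costs, percent identity, and a Karlin-Altschul style
expectation value used as a stand-in for a database search threshold.

Gap convention: a gap run of length L costs ``gap_open + (L - 1) * gap_extend``
(both scores are negative). This matches Biopython's PairwiseAligner, which
provides the optimal scores under the hood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from Bio import Align
from Bio.Align import substitution_matrices

#: Fixed gapped-BLOSUM62 Karlin-Altschul constants (no edge-effect correction).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

MatrixLike = Union[str, substitution_matrices.Array, tuple]


@dataclass(frozen=True)
class Alignment:
    """A scored pairwise alignment.

    ``aligned_a``/``aligned_b`` are gapped strings of equal length; ``matches``
    counts identical residue columns; ``aligned_columns`` counts columns with a
    residue in both rows (gap-free columns).
    """

    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"
    matches: int
    aligned_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("column with gap in both rows")

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class SignificanceParams:
    """Karlin-Altschul parameters for converting a score to an E-value."""

    lambda_ka: float = DEFAULT_LAMBDA
    k_ka: float = DEFAULT_K
    search_space: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_ka <= 0 or self.k_ka <= 0:
            raise ValueError("lambda and K must be positive")
        if self.search_space <= 0:
            raise ValueError("search space must be positive")


def load_matrix(matrix: MatrixLike) -> substitution_matrices.Array:
    """Resolve a substitution matrix.

    Accepts a built-in name ("BLOSUM62"), a path to an NCBI-format matrix
    file, a (match, mismatch) tuple, or an already-loaded Array.
    """
    if isinstance(matrix, substitution_matrices.Array):
        return matrix
    if isinstance(matrix, tuple):
        match, mismatch = matrix
        alphabet = "ACDEFGHIKLMNPQRSTVWYBXZJUO*"
        arr = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                arr[a, b] = match if a == b else mismatch
        return arr
    if isinstance(matrix, str):
        try:
            return substitution_matrices.load(matrix)
        except FileNotFoundError:
            with open(matrix) as handle:
                return substitution_matrices.read(handle)
    raise TypeError(f"cannot interpret substitution matrix: {matrix!r}")


def _aligner(matrix, gap_open, gap_extend, mode):
    if gap_open > 0 or gap_extend > 0:
        raise ValueError("gap penalties are scores and must be <= 0")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner

def _from_biopython(alignment, score, mode):
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    columns = sum(1 for x, y in zip(row_a, row_b) if x != "-" and y != "-")
    return Alignment(row_a, row_b, float(score), mode, matches, columns)


def global_align(
    a: str,
    b: str,
    matrix: MatrixLike = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    Traceback ties are resolved deterministically (first alignment in
    Biopython's fixed enumeration order).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend, "global")
    alignments = aligner.align(a, b)
    return _from_biopython(alignments[0], alignments.score, "global")


def local_align(
    a: str,
    b: str,
    matrix: MatrixLike = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Optimal local alignment; the empty alignment (score 0) is allowed."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(matrix, gap_open, gap_extend, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return Alignment("", "", 0.0, "local", 0, 0)
    return _from_biopython(aligner.align(a, b)[0], score, "local")


def evalue(score: float, params: SignificanceParams) -> float:
    """Expected number of chance hits: ``E = K * m*n * exp(-lambda * S)``."""
    if score <= 0:
        raise ValueError("score must be positive")
    return params.k_ka * params.search_space * math.exp(-params.lambda_ka * score)


def percent_identity(aln: Alignment, denominator: str = "aligned_columns") -> float:
    """Percent identical columns, in [0, 100].

    ``denominator`` selects gap-free columns ("aligned_columns", default) or
    the length of the shorter ungapped sequence ("shorter_seq").
    """
    if aln.length == 0:
        raise ValueError("empty alignment has no identity")
    if denominator == "aligned_columns":
        denom = aln.aligned_columns
    elif denominator == "shorter_seq":
        denom = min(
            len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown denominator: {denominator}")
    if denom == 0:
        raise ValueError("identity denominator is zero")
    return 100.0 * aln.matches / denom
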
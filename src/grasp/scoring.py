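"""Substitution-matrix scoring and search parameters.

All alignment scoring in the package goes through a :class:`ScoringScheme`,
which bundles the substitution matrix, affine gap penalties, the seeding and
overlap parameters, and the Karlin-Altschul statistics used for E-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS, SequenceError

#: Sentinel for out-of-band / unreachable DP cells; large but overflow-safe.
NEG_INF = -(10**9)


def _ord_matrix(mat) -> np.ndarray:
    """Expand a Biopython substitution matrix to a 128x128 ord-indexed array.

    'X' scores the matrix minimum against everything, so ambiguous
    residues never drive seeds or extensions.
    """
    arr = np.full((128, 128), NEG_INF, dtype=np.int64)
    lowest = int(min(mat[a][b] for a in AMINO_ACIDS for b in AMINO_ACIDS))
    for a in AMINO_ACIDS + "X":
        for b in AMINO_ACIDS + "X":
            if "X" in (a, b):
                score = lowest
            else:
                score = int(mat[a][b])
            arr[ord(a), ord(b)] = score
    return arr


def load_matrix(name_or_path: str = "BLOSUM62"):
    """Load a substitution matrix by name or from NCBI matrix text format."""
    if Path(name_or_path).exists():
        with open(name_or_path) as fh:
            return substitution_matrices.read(fh)
    try:
        return substitution_matrices.load(name_or_path.upper())
    except FileNotFoundError as exc:
        raise SequenceError(f"unknown substitution matrix {name_or_path!r}") from exc


@dataclass(frozen=True)
class ScoringScheme:
    """Search parameters and scoring primitives.

    Parameters
    ----------
    matrix_name:
        Substitution matrix (name understood by Biopython, or an NCBI
        matrix text file).
    gap_open, gap_extend:
        Affine gap penalties (positive costs); a gap of length ``g`` costs
        ``gap_open + g * gap_extend``.
    k:
        Seed k-mer length (residues).
    seed_score_min:
        Minimum ungapped full-alphabet score of a seed k-mer pair.
    l:
        Minimum read/path overlap for a supporting read (residues).
    d:
        Alignment band size (cells); must be even, half-width is ``d/2``.
    dropoff:
        Score drop-off X: an extension scoring below (best so far - dropoff)
        is abandoned, as in BLAST.
    min_bridge:
        Minimum number of bridging reads required to merge left and right
        paths.
    evalue_max:
        E-value report cutoff.
    lambda_, K_:
        Karlin-Altschul statistics for gapped BLOSUM62 (11/1) by default.
    m_db:
        Total residue count of the read database (set by the pipeline).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    k: int = 6
    seed_score_min: int = 11
    l: int = 10
    d: int = 40
    dropoff: int = 30
    min_bridge: int = 1
    evalue_max: float = 10.0
    lambda_: float = 0.267
    K_: float = 0.041
    m_db: int = 0

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("k must be >= 3")
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.d < 2 or self.d % 2:
            raise ValueError("band size d must be even and >= 2")
        if self.dropoff <= 0:
            raise ValueError("dropoff must be > 0")
        if self.min_bridge < 1:
            raise ValueError("min_bridge must be >= 1")
        if self.lambda_ <= 0 or self.K_ <= 0:
            raise ValueError("Karlin-Altschul parameters must be > 0")
        object.__setattr__(self, "_mat", _ord_matrix(load_matrix(self.matrix_name)))

    @property
    def matrix(self) -> np.ndarray:
        """Ord-indexed substitution score array (int64)."""
        return self._mat

    @property
    def half_band(self) -> int:
        return self.d // 2

    def sub(self, a: str, b: str) -> int:
        return int(self._mat[ord(a), ord(b)])

    def with_db(self, m_db: int) -> "ScoringScheme":
        return replace(self, m_db=m_db)


def ungapped_score(a: str, b: str, scheme: ScoringScheme) -> int:
    """Sum of positionwise substitution scores of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"ungapped_score: length mismatch ({len(a)} vs {len(b)})")
    if not a:
        return 0
    mat = scheme.matrix
    ia = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    ib = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int(mat[ia, ib].sum())
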
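"""Substitution-matrix services, identity/similarity, and molecular mass.

Identity and similarity follow the BLAST reporting conventions used for
family-comparison tables: identity is the percentage of alignment columns
with identical residues, similarity ("positives") additionally counts
columns whose substitution score is positive, and gap columns stay in the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import protein_weights

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: mass of one water molecule in Da; a peptide is residue masses + one water.
WATER_DA = 18.0153

#: average residue (monomer minus water) masses in Da, from the IUPAC free
#: amino-acid weights.
RESIDUE_MASS_DA = {aa: protein_weights[aa] - WATER_DA for aa in AA_ORDER}

#: Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1.
GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041


def _blosum62_array() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = int(m[a, b])
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap and E-value statistics.

    ``gap_open``/``gap_extend`` use the BLAST convention: a gap of length k
    costs ``gap_open + k * gap_extend``.  ``lam`` and ``K`` are the
    Karlin-Altschul parameters (nats per raw-score unit) used to convert raw
    scores into E-values and bit scores.
    """

    matrix: np.ndarray = field(default_factory=_blosum62_array)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = GAPPED_BLOSUM62_LAMBDA
    K: float = GAPPED_BLOSUM62_K
    name: str = "BLOSUM62/11/1"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        object.__setattr__(self, "matrix", m)

    def score(self, a: str, b: str) -> int:
        """Substitution score for a residue pair; X scores 0 vs anything."""
        if a == "X" or b == "X":
            return 0
        return int(self.matrix[AA_INDEX[a], AA_INDEX[b]])


def load_matrix_ncbi(path: str | Path) -> np.ndarray:
    """Load a substitution matrix in NCBI text format (as shipped with BLAST)."""
    cols: list[str] = []
    rows: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if not cols:
                cols = parts
            else:
                rows[parts[0]] = [int(x) for x in parts[1:]]
    out = np.zeros((20, 20), dtype=np.int64)
    for a in AA_ORDER:
        for b in AA_ORDER:
            out[AA_INDEX[a], AA_INDEX[b]] = rows[a][cols.index(b)]
    return out


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment with 1-based inclusive coordinates."""

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int

    def __post_init__(self) -> None:
        aq, at = self.aligned_query, self.aligned_target
        if len(aq) != len(at):
            raise ValueError("aligned rows must have equal length")
        if any(x == "-" and y == "-" for x, y in zip(aq, at)):
            raise ValueError("column with gap in both rows")
        nq = sum(c != "-" for c in aq)
        nt = sum(c != "-" for c in at)
        if nq and self.q_end - self.q_start + 1 != nq:
            raise ValueError("query coordinates inconsistent with letter count")
        if nt and self.t_end - self.t_start + 1 != nt:
            raise ValueError("target coordinates inconsistent with letter count")

    def __len__(self) -> int:
        return len(self.aligned_query)


def percent_identity_similarity(
    aln: PairwiseAlignment, scheme: ScoringScheme | None = None
) -> tuple[int, int]:
    """Percent identity and similarity of an alignment, rounded to integers.

    identity   = 100 * identical columns / alignment length
    similarity = 100 * (identical or positively scoring columns) / length

    Gap columns count in the denominator of both.
    """
    if len(aln) == 0:
        raise ValueError("zero-length alignment: identity undefined")
    scheme = scheme or ScoringScheme()
    ident = sim = 0
    for a, b in zip(aln.aligned_query, aln.aligned_target):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
            sim += 1
        elif scheme.score(a, b) > 0:
            sim += 1
    n = len(aln)
    return round(100.0 * ident / n), round(100.0 * sim / n)


def raw_identity_similarity(aln: PairwiseAlignment, scheme: ScoringScheme | None = None) -> tuple[float, float]:
    """Unrounded identity/similarity fractions (0..1) of an alignment."""
    if len(aln) == 0:
        raise ValueError("zero-length alignment")
    scheme = scheme or ScoringScheme()
    ident = sim = 0
    for a, b in zip(aln.aligned_query, aln.aligned_target):
        if a == "-" or b == "-":
            continue
        if a == b:
            ident += 1
            sim += 1
        elif scheme.score(a, b) > 0:
            sim += 1
    return ident / len(aln), sim / len(aln)


def average_mass(sequence: str) -> float:
    """Average molecular mass of a peptide in kDa (1 decimal of kDa is the
    conventional reporting precision).

    Sum of average residue masses plus one water.  ``X`` and empty sequences
    are rejected: their mass is undefined.
    """
    if not sequence:
        raise ValueError("mass of the empty sequence is undefined")
    total = WATER_DA
    for aa in sequence:
        try:
            total += RESIDUE_MASS_DA[aa]
        except KeyError:
            raise ValueError(f"mass undefined for residue {aa!r}") from None
    return total / 1000.0
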
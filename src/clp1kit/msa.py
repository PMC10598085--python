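"""Progressive multiple alignment, conservation ranks, and gap trimming.

The aligner is a classic progressive scheme: a k-mer-distance guide tree
(average linkage) determines the merge order, and profiles are merged with
an affine-gap (Gotoh) profile-profile dynamic programme under the same
BLOSUM62 scheme used elsewhere, with free terminal gaps.  For two sequences
this reduces to the optimal global pairwise alignment.

Column conservation follows the physicochemical-property scheme of
alignment viewers: each column gets one of 12 ranks (0-11), where 11 means
all residues identical (symbol ``*``), 10 means gap-free with every
physicochemical property conserved across the column (symbol ``+``), and
otherwise the rank is the number of properties that are uniformly present
or uniformly absent among the residues, capped at 9 whenever the column
contains a gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage

from .records import ProteinRecord
from .scoring import AA_INDEX, AA_ORDER, ScoringScheme

GAP = "-"

#: physicochemical property sets (Taylor / Livingstone-Barton classification)
PROPERTY_SETS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "polar": frozenset("YWHKREQDNSTC"),
    "charged": frozenset("HKRED"),
    "positive": frozenset("HKR"),
    "negative": frozenset("ED"),
    "small": frozenset("VCAGDNSTP"),
    "tiny": frozenset("AGS"),
    "proline": frozenset("P"),
}

_PROP_MATRIX = np.zeros((21, len(PROPERTY_SETS)), dtype=bool)  # 20 aa + X
for _p, (_name, _members) in enumerate(sorted(PROPERTY_SETS.items())):
    for _aa in _members:
        _PROP_MATRIX[AA_INDEX[_aa], _p] = True


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows keyed by sequence id, in a fixed order."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row_for(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def write_alignment_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in zip(aln.ids, aln.rows):
            fh.write(f">{i}\n{row}\n")


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    ids, rows, cur = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            elif line:
                cur.append(line)
    if cur:
        rows.append("".join(cur))
    return MultipleAlignment(tuple(ids), tuple(rows))


def write_alignment_stockholm(aln: MultipleAlignment, path: str | Path) -> None:
    width = max(len(i) for i in aln.ids) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for i, row in zip(aln.ids, aln.rows):
            fh.write(f"{i:<{width}}{row}\n")
        fh.write("//\n")


def read_alignment_stockholm(path: str | Path) -> MultipleAlignment:
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "//")):
                continue
            name, row = line.split()
            ids.append(name)
            rows.append(row.replace(".", GAP).upper())
    return MultipleAlignment(tuple(ids), tuple(rows))


# ---------------------------------------------------------------------------
# profile-profile Gotoh DP (numba-compiled)

NEG = -1e30


@njit(cache=True)
def _gotoh_profile(S, gap_open, gap_ext):  # pragma: no cover - compiled
    """Semi-global affine DP on a pair score matrix; returns (score, traceback).

    Terminal gaps are free.  Traceback codes: 0 diagonal, 1 up (gap in
    second profile), 2 left (gap in first profile).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    tbM = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbX = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0  # free leading gap
        tbX[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = 0.0
        tbY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M state
            best = M[i - 1, j - 1]
            code = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                code = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                code = 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = code
            # Ix: gap in second profile (consume row i)
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_ext
            if a >= b:
                Ix[i, j] = a
                tbX[i, j] = 0
            else:
                Ix[i, j] = b
                tbX[i, j] = 1
            # Iy: gap in first profile (consume column j)
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_ext
            if a >= b:
                Iy[i, j] = a
                tbY[i, j] = 0
            else:
                Iy[i, j] = b
                tbY[i, j] = 2
    # free trailing gaps: best M over last row / last column
    bi, bj, bs = n, m, max(M[n, m], Ix[n, m], Iy[n, m])
    for i in range(0, n + 1):
        if M[i, m] > bs:
            bs = M[i, m]
            bi, bj = i, m
    for j in range(0, m + 1):
        if M[n, j] > bs:
            bs = M[n, j]
            bi, bj = n, j
    return bs, bi, bj, M, Ix, Iy, tbM, tbX, tbY


def _traceback(bi, bj, n, m, M, Ix, Iy, tbM, tbX, tbY) -> list[int]:
    ops: list[int] = []
    # trailing free gaps
    for _ in range(m - bj):
        ops.append(2)
    for _ in range(n - bi):
        ops.append(1)
    i, j = bi, bj
    if i == n and j == m:
        state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    else:
        state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                # remaining leading gaps
                while j > 0:
                    ops.append(2)
                    j -= 1
                while i > 0:
                    ops.append(1)
                    i -= 1
                break
            code = tbM[i, j]
            ops.append(0)
            i -= 1
            j -= 1
            state = code
        elif state == 1:
            code = tbX[i, j]
            ops.append(1)
            i -= 1
            state = code
        else:
            code = tbY[i, j]
            ops.append(2)
            j -= 1
            state = code
    ops.reverse()
    return ops


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Residue-frequency profile, shape (L, 20); gaps contribute nothing."""
    L = len(rows[0])
    out = np.zeros((L, 20), dtype=np.float64)
    for row in rows:
        for j, c in enumerate(row):
            if c == GAP:
                continue
            if c == "X":
                out[j, :] += 1.0 / 20.0
            else:
                out[j, AA_INDEX[c]] += 1.0
    out /= len(rows)
    return out


def _align_profiles(
    rows_a: Sequence[str], rows_b: Sequence[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    fa = _profile(rows_a)
    fb = _profile(rows_b)
    sub = scheme.matrix.astype(np.float64)
    S = fa @ sub @ fb.T
    go = float(scheme.gap_open + scheme.gap_extend)
    ge = float(scheme.gap_extend)
    bs, bi, bj, M, Ix, Iy, tbM, tbX, tbY = _gotoh_profile(S, go, ge)
    ops = _traceback(bi, bj, S.shape[0], S.shape[1], M, Ix, Iy, tbM, tbX, tbY)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    bufa = [[] for _ in rows_a]
    bufb = [[] for _ in rows_b]
    for op in ops:
        if op == 0:
            for k, r in enumerate(rows_a):
                bufa[k].append(r[ia])
            for k, r in enumerate(rows_b):
                bufb[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == 1:
            for k, r in enumerate(rows_a):
                bufa[k].append(r[ia])
            for k in range(len(rows_b)):
                bufb[k].append(GAP)
            ia += 1
        else:
            for k in range(len(rows_a)):
                bufa[k].append(GAP)
            for k, r in enumerate(rows_b):
                bufb[k].append(r[ib])
            ib += 1
    out_a = ["".join(b) for b in bufa]
    out_b = ["".join(b) for b in bufb]
    return out_a, out_b


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    sets = [frozenset(s[i:i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - shared
    return d


def progressive_msa(
    records: Sequence[ProteinRecord], scheme: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment; deterministic for a fixed input order."""
    if len(records) < 2:
        raise ValueError("need at least two sequences to align")
    scheme = scheme or ScoringScheme()
    seqs = [r.sequence for r in records]
    n = len(seqs)
    d = _kmer_distance_matrix(seqs)
    iu = np.triu_indices(n, 1)
    Z = linkage(d[iu], method="average")
    # active[i] -> (ids, rows)
    active: dict[int, tuple[list[str], list[str]]] = {
        i: ([records[i].id], [seqs[i]]) for i in range(n)
    }
    for step, (a, b, _dist, _cnt) in enumerate(Z):
        ia, ib = int(a), int(b)
        ids_a, rows_a = active.pop(ia)
        ids_b, rows_b = active.pop(ib)
        new_a, new_b = _align_profiles(rows_a, rows_b, scheme)
        active[n + step] = (ids_a + ids_b, new_a + new_b)
    (ids, rows), = active.values()
    order = {r.id: i for i, r in enumerate(records)}
    pairs = sorted(zip(ids, rows), key=lambda p: order[p[0]])
    return MultipleAlignment(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


# ---------------------------------------------------------------------------
# conservation and trimming

RANK_IDENTICAL = 11
RANK_ALL_PROPERTIES = 10


def conservation_ranks(aln: MultipleAlignment) -> list[tuple[int, str]]:
    """Per-column (rank, symbol): 11 ``*`` identical, 10 ``+`` all-property
    conserved, else 0-9 (a gap caps the rank at 9)."""
    out = []
    for j in range(aln.n_columns):
        col = aln.column(j)
        residues = [c for c in col if c != GAP]
        has_gap = len(residues) < len(col)
        if not residues:
            out.append((0, " "))
            continue
        if not has_gap and len(set(residues)) == 1:
            out.append((RANK_IDENTICAL, "*"))
            continue
        vecs = np.array([_PROP_MATRIX[AA_INDEX.get(c, 20)] for c in residues])
        conserved = int(np.sum(vecs.all(axis=0) | (~vecs).all(axis=0)))
        if not has_gap and conserved == _PROP_MATRIX.shape[1]:
            out.append((RANK_ALL_PROPERTIES, "+"))
        else:
            out.append((min(conserved, 9), str(min(conserved, 9))))
    return out


def trim_alignment(
    aln: MultipleAlignment, gap_fraction_max: float = 0.0
) -> tuple[MultipleAlignment, list[int]]:
    """Remove columns whose gap fraction exceeds the threshold.

    The default 0.0 removes every column containing any gap.  Returns the
    trimmed alignment and the list of retained original column indices
    (0-based provenance map).
    """
    n_rows = len(aln.rows)
    keep = []
    for j in range(aln.n_columns):
        gaps = sum(1 for r in aln.rows if r[j] == GAP)
        if gaps / n_rows <= gap_fraction_max:
            keep.append(j)
    if not keep:
        raise ValueError(
            "trimming removed all columns; raise gap_fraction_max")
    rows = tuple("".join(r[j] for j in keep) for r in aln.rows)
    return MultipleAlignment(aln.ids, rows), keep
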
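"""Greedy representative clustering (CD-HIT-style semantics).

Records are sorted by decreasing length and each joins the first existing
cluster whose representative it matches at or above the identity threshold,
where identity is the number of identical positions in a global alignment
divided by the shorter sequence length.  Otherwise it founds a new cluster.
The ordering is re-derived internally, so the result does not depend on the
input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import ProteinRecord
from .scoring import ScoringScheme
from .search import align_global


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]
    threshold: float


def pairwise_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Identical positions in the global alignment / shorter sequence length."""
    scheme = scheme or ScoringScheme()
    aln = align_global(a, b, scheme)
    ident = sum(1 for x, y in zip(aln.aligned_query, aln.aligned_target)
                if x != "-" and x == y)
    return ident / min(len(a), len(b))


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float = 0.70,
    scheme: ScoringScheme | None = None,
) -> list[Cluster]:
    if not records:
        raise ValueError("no records to cluster")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    scheme = scheme or ScoringScheme()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        placed = False
        for i, rep in enumerate(reps):
            if pairwise_identity(rec.sequence, rep.sequence, scheme) >= threshold:
                members[i].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
    return [
        Cluster(representative_id=rep.id, member_ids=tuple(ms), threshold=threshold)
        for rep, ms in zip(reps, members)
    ]


def representative_set(
    clusters: Sequence[Cluster],
    records: Sequence[ProteinRecord],
    anchors: Sequence[str] = (),
) -> list[ProteinRecord]:
    """Cluster representatives plus required anchor records re-added.

    Mirrors how a representative sequence set is assembled for phylogenetics:
    one sequence per cluster, with reference members of known identity added
    back even when they were absorbed into a cluster.
    """
    by_id = {r.id: r for r in records}
    ids = [c.representative_id for c in clusters]
    for a in anchors:
        if a not in by_id:
            raise KeyError(f"anchor {a!r} not among records")
        if a not in ids:
            ids.append(a)
    return [by_id[i] for i in ids]
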
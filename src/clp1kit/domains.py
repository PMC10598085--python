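"""Domain annotation: PSSM profile scans plus novel-domain discovery.

Two routes mirror how family domain structures are annotated in practice:
(1) known domains are located with position-specific scoring models built
from seed alignments and thresholded on an E-value from a fitted Gumbel
null; (2) regions left unannotated are compared all-against-all with the
local-alignment search, and single-linkage components of mutually similar
segments that recur across enough proteins and species are promoted to
named novel domains, with boundaries refined on the component alignment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from .msa import GAP, MultipleAlignment, progressive_msa
from .records import ProteinRecord
from .scoring import AA_INDEX, AA_ORDER
from .search import SearchParams, search_local

#: Robinson & Robinson background amino-acid frequencies (order ACDEFGHIKLMNPQRSTVWY)
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: null-model calibration: number and length of background sequences
NULL_N_SEQS = 200
NULL_SEQ_LEN = 400


@dataclass(frozen=True)
class DomainProfile:
    """Per-column log-odds scores (log2) for one domain model."""

    name: str
    scores: np.ndarray  # (length, 20)
    source: str = "seed-alignment"
    null_loc: float = 0.0
    null_scale: float = 1.0

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_name: str
    start: int  # 1-based inclusive
    end: int
    score: float
    evalue: float
    origin: str  # "profile" | "novel"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid domain coordinates")

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def _seq_to_idx(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def build_profile(seed: MultipleAlignment, name: str = "profile") -> DomainProfile:
    """Log-odds PSSM from a seed alignment.

    Columns with more than 50% gaps are excluded from the model; residue
    frequencies are smoothed with background-proportional pseudocounts
    (total pseudocount mass 20, i.e. plain add-one under a uniform
    background), so that on an all-identical seed each column's top-scoring
    residue is the observed one.
    """
    if len(seed.rows) < 2:
        raise ValueError("profile seed needs at least two rows")
    n = len(seed.rows)
    cols = []
    for j in range(seed.n_columns):
        col = seed.column(j)
        if col.count(GAP) / n > 0.5:
            continue
        counts = np.zeros(20)
        for c in col:
            if c == GAP:
                continue
            if c == "X":
                counts += 1.0 / 20.0
            else:
                counts[AA_INDEX[c]] += 1.0
        freqs = (counts + 20.0 * BACKGROUND) / (counts.sum() + 20.0)
        cols.append(np.log2(freqs / BACKGROUND))
    if len(cols) < 1:
        raise ValueError("seed alignment has no usable columns")
    scores = np.vstack(cols)
    pool = np.array([AA_INDEX[c] for row in seed.rows for c in row
                     if c in AA_INDEX], dtype=np.int64)
    loc, scale = _calibrate_null(name, scores, pool)
    return DomainProfile(name=name, scores=scores, null_loc=loc, null_scale=scale)


def _calibrate_null(name: str, scores: np.ndarray,
                    pool: np.ndarray) -> tuple[float, float]:
    """Fit a Gumbel to best-placement scores on shuffled-composition nulls.

    Null sequences are drawn from the residue composition of the seed
    alignment itself (not the genome-wide background), which keeps the null
    honest for sequences whose composition resembles the domain family's.
    """
    seed = zlib.crc32(name.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    L = scores.shape[0]
    n = max(NULL_SEQ_LEN, L)
    maxima = []
    for _ in range(NULL_N_SEQS):
        idx = rng.choice(pool, size=n, replace=True)
        s, _, _, _ = _best_local_placement(scores, idx)
        maxima.append(s)
    loc, scale = gumbel_r.fit(maxima)
    return float(loc), float(max(scale, 1e-6))


@njit(cache=True)
def _best_placement_jit(scores, col_means, seq_idx):  # pragma: no cover - compiled
    L = scores.shape[0]
    n = seq_idx.shape[0]
    best_score = -1e30
    best_k = 0
    best_j = 0
    best_len = 0
    for d in range(-L + 1, n):
        k0 = max(0, -d)
        k1 = min(L, n - d)
        if k1 - k0 < 1:
            continue
        run = 0.0
        run_start = k0
        for k in range(k0, k1):
            j = k + d
            si = seq_idx[j]
            v = col_means[k] if si < 0 else scores[k, si]
            if run <= 0.0:
                run = v
                run_start = k
            else:
                run += v
            if run > best_score:
                best_score = run
                best_k = run_start
                best_j = run_start + d
                best_len = k - run_start + 1
    return best_score, best_k, best_j, best_len


def _best_local_placement(
    scores: np.ndarray, seq_idx: np.ndarray
) -> tuple[float, int, int, int]:
    """Best ungapped local placement of the profile along the sequence.

    The profile may match with a contiguous subset of its columns (partial
    placements score only the columns they use), which lets truncated domain
    instances report their true, shorter extent.  Returns
    (score, profile_start, sequence_start, matched_length), 0-based.
    Implemented as Kadane's maximum-subarray scan along every diagonal.
    """
    s, k, j, ln = _best_placement_jit(
        np.ascontiguousarray(scores, dtype=np.float64),
        scores.mean(axis=1).astype(np.float64),
        np.ascontiguousarray(seq_idx, dtype=np.int64),
    )
    return float(s), int(k), int(j), int(ln)


def profile_evalue(profile: DomainProfile, score: float, protein_len: int) -> float:
    """Expected number of equal-or-better placements in a protein this long.

    The Gumbel null was calibrated on background sequences of a reference
    length; the tail probability scales linearly with the scanned length.
    """
    p = float(gumbel_r.sf(score, loc=profile.null_loc, scale=profile.null_scale))
    return p * max(protein_len, 1) / NULL_SEQ_LEN


def scan_profiles(
    protein: ProteinRecord,
    profiles: Sequence[DomainProfile],
    evalue_max: float = 1e-3,
    min_profile_fraction: float = 0.5,
) -> list[DomainHit]:
    """Best local placement per profile; E-value thresholded; fragmentary
    placements (matching under half the model's columns) discarded;
    overlaps resolved best-score-first."""
    if not protein.sequence:
        raise ValueError("empty protein")
    idx = _seq_to_idx(protein.sequence)
    candidates: list[DomainHit] = []
    for prof in profiles:
        if prof.length > len(protein.sequence):
            continue  # a model longer than the protein yields no hit
        score, k, j, ln = _best_local_placement(prof.scores, idx)
        e = profile_evalue(prof, score, len(protein.sequence))
        if e <= evalue_max and ln >= min_profile_fraction * prof.length:
            start, end = j + 1, j + ln
            if ln >= 0.9 * prof.length:
                # near-complete placements are reported glocally: the few
                # weakly scoring end columns still belong to the domain
                start = max(1, j + 1 - k)
                end = min(len(protein.sequence), start + prof.length - 1)
            candidates.append(DomainHit(
                protein_id=protein.id, domain_name=prof.name,
                start=start, end=end,
                score=score, evalue=e, origin="profile",
            ))
    return resolve_overlaps(candidates)


#: a lower-scoring hit may lose at most this fraction of itself to trimming
#: before it is dropped outright
MAX_TRIM_FRACTION = 0.5
MIN_HIT_LEN = 10


def _merge_hits(accepted: list[DomainHit], candidates: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedily add candidates (already priority-ordered) to the accepted
    set: overlaps up to half of the candidate's length are trimmed off the
    candidate, larger conflicts drop it."""
    out = list(accepted)
    for h in candidates:
        trimmed = h
        ok = True
        for a in out:
            ov = trimmed.overlap(a)
            if ov == 0:
                continue
            if ov > MAX_TRIM_FRACTION * (trimmed.end - trimmed.start + 1):
                ok = False
                break
            if trimmed.start < a.start:
                new_end = a.start - 1
                if new_end - trimmed.start + 1 < MIN_HIT_LEN:
                    ok = False
                    break
                trimmed = DomainHit(trimmed.protein_id, trimmed.domain_name,
                                    trimmed.start, new_end, trimmed.score,
                                    trimmed.evalue, trimmed.origin)
            else:
                new_start = a.end + 1
                if trimmed.end - new_start + 1 < MIN_HIT_LEN:
                    ok = False
                    break
                trimmed = DomainHit(trimmed.protein_id, trimmed.domain_name,
                                    new_start, trimmed.end, trimmed.score,
                                    trimmed.evalue, trimmed.origin)
        if ok:
            out.append(trimmed)
    out.sort(key=lambda h: h.start)
    return out


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Best-score-first overlap resolution; deterministic tie-break by
    (score desc, name, start)."""
    ordered = sorted(hits, key=lambda h: (-h.score, h.domain_name, h.start))
    return _merge_hits([], ordered)


def unannotated_segments(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    min_len: int = 50,
) -> list[tuple[int, int]]:
    """Maximal intervals not covered by any hit, of length >= min_len
    (1-based inclusive coordinates)."""
    n = len(protein.sequence)
    covered = np.zeros(n + 2, dtype=bool)
    for h in hits:
        covered[h.start:h.end + 1] = True
    out = []
    start = None
    for pos in range(1, n + 1):
        if not covered[pos]:
            if start is None:
                start = pos
        elif start is not None:
            if pos - start >= min_len:
                out.append((start, pos - 1))
            start = None
    if start is not None and n - start + 1 >= min_len:
        out.append((start, n))
    return out


@dataclass(frozen=True)
class Segment:
    """An unannotated protein region submitted to novel-domain discovery."""
    protein_id: str
    species: str
    start: int
    end: int
    sequence: str

    @property
    def seg_id(self) -> str:
        return f"{self.protein_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class NovelDomain:
    name: str
    members: tuple[DomainHit, ...]
    mean_length: float
    sd_length: float
    n_species: int


def discover_novel_domains(
    segments: Sequence[Segment],
    evalue_max: float = 1e-4,
    coverage_min: float = 0.30,
    min_members: int = 3,
    min_species: int = 3,
    params: SearchParams | None = None,
) -> list[NovelDomain]:
    """Cluster mutually similar unannotated segments into novel domains.

    All-vs-all local alignment; an edge joins two segments when any directed
    comparison passes both the E-value and query-coverage thresholds.
    Single-linkage connected components with enough members from enough
    species become domains (named NDOM1, NDOM2, ... by decreasing size).
    Member boundaries are refined to the aligned core: columns of the
    component alignment covered by at least half of the members.
    """
    if len(segments) < 2:
        return []
    params = params or SearchParams(evalue_max=evalue_max, coverage_min=coverage_min)
    seg_records = [ProteinRecord(id=s.seg_id, sequence=s.sequence, species=s.species)
                   for s in segments]
    by_id = {s.seg_id: s for s in segments}
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for q in seg_records:
        db = [t for t in seg_records if t.id != q.id]
        for h in search_local(q, db, params):
            g.add_edge(q.id, h.target_id)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps = [c for c in comps
             if len(c) >= min_members
             and len({by_id[s].species for s in c}) >= min_species]
    comps.sort(key=lambda c: (-len(c), c[0]))
    out: list[NovelDomain] = []
    for i, comp in enumerate(comps, start=1):
        name = f"NDOM{i}"
        segs = [by_id[s] for s in comp]
        members = _refined_members(name, segs)
        lengths = np.array([h.end - h.start + 1 for h in members], dtype=float)
        out.append(NovelDomain(
            name=name,
            members=tuple(sorted(members, key=lambda h: h.protein_id)),
            mean_length=float(lengths.mean()),
            sd_length=float(lengths.std()),
            n_species=len({s.species for s in segs}),
        ))
    return out


def _refined_members(name: str, segs: Sequence[Segment]) -> list[DomainHit]:
    recs = [ProteinRecord(id=s.seg_id, sequence=s.sequence) for s in segs]
    aln = progressive_msa(recs)
    n = len(aln.rows)
    core_cols = [j for j in range(aln.n_columns)
                 if sum(1 for r in aln.rows if r[j] != GAP) >= 0.5 * n]
    hits = []
    for s in segs:
        row = aln.row_for(s.seg_id)
        # residue index (0-based within the segment) at each column
        res_at = np.cumsum([c != GAP for c in row]) - 1
        core_res = [res_at[j] for j in core_cols if row[j] != GAP]
        if not core_res:
            continue
        start = s.start + int(core_res[0])
        end = s.start + int(core_res[-1])
        hits.append(DomainHit(
            protein_id=s.protein_id, domain_name=name,
            start=start, end=end, score=0.0, evalue=0.0, origin="novel",
        ))
    return hits


@dataclass(frozen=True)
class Architecture:
    """Ordered, non-overlapping domains of one protein."""
    protein_id: str
    hits: tuple[DomainHit, ...]

    @property
    def string(self) -> str:
        return "|".join(h.domain_name for h in self.hits)

    def span_of(self, domain_name: str) -> tuple[int, int] | None:
        for h in self.hits:
            if h.domain_name == domain_name:
                return h.start, h.end
        return None


def assemble_architecture(
    protein: ProteinRecord,
    profile_hits: Sequence[DomainHit],
    novel_hits: Sequence[DomainHit] = (),
) -> Architecture:
    """Union of profile and novel hits; overlaps resolved profile-first, then
    best-score, tie-broken by domain name; hits ordered by start."""
    prof = resolve_overlaps(list(profile_hits))
    novel = sorted(novel_hits, key=lambda h: (-h.score, h.domain_name, h.start))
    merged = _merge_hits(prof, novel)
    return Architecture(protein_id=protein.id, hits=tuple(merged))


def write_domain_hits_tsv(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain\tstart\tend\tscore\tevalue\torigin\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_name}\t{h.start}\t{h.end}\t"
                     f"{h.score:.2f}\t{h.evalue:.3g}\t{h.origin}\n")


def read_domain_hits_tsv(path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            p, d, s, e, sc, ev, o = line.rstrip("\n").split("\t")
            hits.append(DomainHit(p, d, int(s), int(e), float(sc), float(ev), o))
    return hits
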
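"""Family classification: groups from the kinase-domain tree, paralog types,
PNK motifs, and activity prediction.

The family splits into two groups (Clp1 vs Nol9/Grc3) that separate as the
two subtrees under the midpoint root of a tree built on the central kinase
(Clp1_P) domain; reference anchor proteins of known membership label the
subtrees.  Within a group, cross-species clades whose members share a
domain-architecture signature become numbered "types" (t1, t2, ...), while
co-occurring same-species paralogs that form no such clade get letter
suffixes (-a, -b, -c).  Polynucleotide-kinase activity is predicted from
the four catalytic-site motifs (Walker A, Walker B, Clasp, Lid) together
with a minimum kinase-domain length of 130 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from skbio import TreeNode

from .records import ProteinRecord
from .scoring import percent_identity_similarity
from .search import SearchParams, search_local

GROUP_CLP1 = "Clp1"
GROUP_NOL9 = "Nol9/Grc3"
UNKNOWN = "unknown"

ANY = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifModel:
    """A position-restricted residue-class pattern for one catalytic motif."""

    name: str
    pattern: tuple[str, ...]  # allowed residues per position
    max_mismatches: int = 0
    order_index: int = 0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def mismatches(self, window: str) -> int:
        return sum(1 for c, allowed in zip(window, self.pattern) if c not in allowed)


#: canonical motif instances planted by the simulator and used to derive the
#: default patterns; the Clasp/Lid consensus is a stand-in that users can
#: override with their own reference-derived patterns.
CANONICAL_MOTIFS = {
    "WalkerA": "GSAGTGKS",
    "WalkerB": "ILVFDE",
    "Clasp": "RWVEHG",
    "Lid": "RKTEFG",
}

DEFAULT_MOTIFS: tuple[MotifModel, ...] = (
    MotifModel("WalkerA", ("AG", ANY, ANY, ANY, ANY, "G", "K", "ST"), 0, 0),
    MotifModel("WalkerB", ("ILVMF", "ILVMF", "ILVMF", "ILVMF", "DE", "DE"), 0, 1),
    MotifModel("Clasp", ("RK", "W", "ILV", "DE", "H", "G"), 0, 2),
    MotifModel("Lid", ("RK", "K", "T", "DE", "FY", "G"), 0, 3),
)


@dataclass(frozen=True)
class MotifMatch:
    name: str
    matched: bool
    position: int | None  # 1-based within the scanned span
    matched_string: str | None


@dataclass(frozen=True)
class FamilyCall:
    """Final per-protein classification row."""

    protein_id: str
    species: str
    group: str
    type_label: str  # "t1", "a", or ""
    architecture: str
    motif_report: tuple[MotifMatch, ...]
    clp1p_length: int | None
    predicted_activity: str  # active | inactive | unknown
    duplicate_in_clade: bool = False
    length: int = 0
    n_isoforms: int = 0


def scan_motifs(
    span: str, models: Sequence[MotifModel] = DEFAULT_MOTIFS
) -> tuple[MotifMatch, ...]:
    """Locate each motif at its best position, respecting the expected
    left-to-right order along the kinase domain.

    The best position is the one with the fewest pattern mismatches
    (leftmost wins ties) at or after the end of the previous matched motif;
    a motif matches when its mismatch count is within the model's budget.
    """
    report: list[MotifMatch] = []
    cursor = 0
    for model in sorted(models, key=lambda m: m.order_index):
        if not span or cursor + model.length > len(span):
            report.append(MotifMatch(model.name, False, None, None))
            continue
        best_pos, best_mm = None, None
        for pos in range(cursor, len(span) - model.length + 1):
            mm = model.mismatches(span[pos:pos + model.length])
            if best_mm is None or mm < best_mm:
                best_pos, best_mm = pos, mm
                if mm == 0:
                    break
        matched = best_mm is not None and best_mm <= model.max_mismatches
        if matched:
            report.append(MotifMatch(model.name, True, best_pos + 1,
                                     span[best_pos:best_pos + model.length]))
            cursor = best_pos + model.length
        else:
            report.append(MotifMatch(model.name, False, None, None))
    return tuple(report)


MIN_ACTIVE_KINASE_LEN = 130


def predict_activity(
    report: Sequence[MotifMatch], clp1p_length: int | None
) -> str:
    """'active' iff all four motifs matched and the kinase domain is at least
    130 aa long; 'unknown' when the domain was not located."""
    if clp1p_length is None:
        return UNKNOWN
    if clp1p_length < MIN_ACTIVE_KINASE_LEN:
        return "inactive"
    if all(m.matched for m in report):
        return "active"
    return "inactive"


class GroupSplitError(RuntimeError):
    """The rooted tree does not bipartition the anchor groups."""


def split_groups(
    rooted_tree: TreeNode, anchors: Mapping[str, str]
) -> dict[str, str]:
    """Label every leaf by the majority anchor membership of its root-child
    subtree.  Leaves in a subtree without anchors are 'unknown'."""
    children = rooted_tree.children
    if len(children) < 2:
        raise ValueError("tree must be rooted with at least two subtrees")
    groups = set(anchors.values())
    if not groups:
        raise ValueError("need at least one anchor per group")
    subtree_label: list[str | None] = []
    leafsets: list[list[str]] = []
    for ch in children:
        leaves = [t.name for t in ch.tips()] if not ch.is_tip() else [ch.name]
        leafsets.append(leaves)
        counts: dict[str, int] = {}
        for leaf in leaves:
            if leaf in anchors:
                counts[anchors[leaf]] = counts.get(anchors[leaf], 0) + 1
        if not counts:
            subtree_label.append(None)
            continue
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            raise GroupSplitError(
                f"anchor groups tied within one subtree: {counts}")
        subtree_label.append(ranked[0][0])
    labelled = [l for l in subtree_label if l is not None]
    if len(set(labelled)) < len(labelled):
        raise GroupSplitError(
            "both anchor groups fall into the same subtree; the rooted tree "
            "does not separate the groups")
    out: dict[str, str] = {}
    for label, leaves in zip(subtree_label, leafsets):
        for leaf in leaves:
            out[leaf] = label if label is not None else UNKNOWN
    return out


@dataclass(frozen=True)
class TypeAssignment:
    labels: dict[str, str]  # id -> "t1" | "a" | ""
    flagged_duplicates: frozenset[str]
    type_clades: dict[str, tuple[str, ...]]  # type label -> member ids


def assign_types(
    member_ids: Sequence[str],
    species_of: Mapping[str, str],
    tree: TreeNode,
    architectures: Mapping[str, str],
) -> TypeAssignment:
    """Assign cross-species type labels and same-species letter suffixes.

    A *type* is a maximal clade whose leaves (i) come from at least two
    species, (ii) include at most one member per species (a single extra
    same-species duplicate is tolerated and flagged), and (iii) share a
    domain-architecture signature not shared by another such clade in the
    group.  Types are numbered t1..tn by decreasing clade size (ties by the
    alphabetically first member id).  Remaining same-species co-occurring
    members get -a, -b, -c suffixes in input order; singletons stay bare.
    """
    members = set(member_ids)
    tip_names = {t.name for t in tree.tips()}
    missing = members - tip_names
    if missing:
        raise KeyError(f"members absent from tree: {sorted(missing)}")

    # types and suffixes only distinguish multiple same-species paralogs;
    # a species' sole group member keeps its bare name
    per_sp_count: dict[str, int] = {}
    for m in member_ids:
        sp = species_of[m]
        per_sp_count[sp] = per_sp_count.get(sp, 0) + 1
    if max(per_sp_count.values(), default=0) <= 1:
        return TypeAssignment(labels={m: "" for m in member_ids},
                              flagged_duplicates=frozenset(), type_clades={})

    qualifying: list[tuple[TreeNode, tuple[str, ...], bool]] = []
    for node in tree.non_tips(include_self=True):
        leaves = tuple(sorted(t.name for t in node.tips()))
        if not set(leaves) <= members or len(leaves) < 2:
            continue
        species_counts: dict[str, int] = {}
        for l in leaves:
            sp = species_of[l]
            species_counts[sp] = species_counts.get(sp, 0) + 1
        if len(species_counts) < 2:
            continue
        extras = sum(c - 1 for c in species_counts.values() if c > 1)
        if extras > 1 or max(species_counts.values()) > 2:
            continue
        sigs = {architectures.get(l, "") for l in leaves}
        if len(sigs) != 1:
            continue
        qualifying.append((node, leaves, extras == 1))

    # keep maximal qualifying clades only
    leaf_sets = [set(l) for _, l, _ in qualifying]
    maximal = [q for q, ls in zip(qualifying, leaf_sets)
               if not any(ls < other for other in leaf_sets)]

    # signature must be unique among maximal clades
    sig_of = {leaves: architectures.get(leaves[0], "") for _, leaves, _ in maximal}
    sig_counts: dict[str, int] = {}
    for s in sig_of.values():
        sig_counts[s] = sig_counts.get(s, 0) + 1
    typed = [(node, leaves, dup) for node, leaves, dup in maximal
             if sig_counts[sig_of[leaves]] == 1]

    typed.sort(key=lambda q: (-len(q[1]), q[1][0]))
    labels: dict[str, str] = {}
    flagged: set[str] = set()
    type_clades: dict[str, tuple[str, ...]] = {}
    for i, (node, leaves, has_dup) in enumerate(typed, start=1):
        t = f"t{i}"
        type_clades[t] = leaves
        for l in leaves:
            labels[l] = t
        if has_dup:
            sp_seen: dict[str, str] = {}
            for l in leaves:
                sp = species_of[l]
                if sp in sp_seen:
                    flagged.add(l)
                    flagged.add(sp_seen[sp])
                sp_seen[sp] = l

    remaining = [m for m in member_ids if m not in labels]
    per_species: dict[str, list[str]] = {}
    for m in remaining:
        per_species.setdefault(species_of[m], []).append(m)
    for sp, ms in per_species.items():
        if len(ms) == 1:
            labels[ms[0]] = ""
        else:
            for i, m in enumerate(ms):
                labels[m] = chr(ord("a") + i)
    return TypeAssignment(labels=labels, flagged_duplicates=frozenset(flagged),
                          type_clades=type_clades)


DASH = "–"  # en dash used on the matrix diagonal
ND = "N/D"


def identity_matrix(
    members: Sequence[ProteinRecord],
    params: SearchParams | None = None,
) -> pd.DataFrame:
    """Round-robin "identity (similarity)" matrix between family members.

    Cell (query, target) holds the integer identity and similarity
    percentages of the best local alignment when it passes the search
    thresholds, the literal "N/D" when no hit passes, and an en dash on the
    diagonal.  The matrix may be asymmetric because alignments are
    query-dependent.
    """
    if len(members) < 2:
        raise ValueError("need at least two members")
    params = params or SearchParams()
    ids = [m.id for m in members]
    data = {}
    for q in members:
        row = []
        for t in members:
            if q.id == t.id:
                row.append(DASH)
                continue
            hits = search_local(q, [t], params)
            if hits:
                h = hits[0]
                row.append(f"{h.identity_pct} ({h.positive_pct})")
            else:
                row.append(ND)
        data[q.id] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=ids)


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="query")


def protein_display_name(call: FamilyCall) -> str:
    """Conventional protein name: species prefix, group, type/suffix."""
    base = "Clp1" if call.group == GROUP_CLP1 else "Nol9/Grc3"
    if call.group == UNKNOWN:
        base = "Clp1fam"
    label = f"-{call.type_label}" if call.type_label else ""
    return f"{call.species}-{base}{label}"


def write_calls_tsv(calls: Sequence[FamilyCall], path) -> None:
    """Per-protein classification table (species, name, group, type, ...)."""
    with open(path, "w") as fh:
        fh.write("species\tprotein_name\tprotein_id\tlength\tgroup\ttype\t"
                 "architecture\tclp1p_length\tmotifs_matched\t"
                 "predicted_activity\tn_isoforms\n")
        for c in calls:
            nm = sum(1 for m in c.motif_report if m.matched)
            fh.write("\t".join(str(x) for x in (
                c.species, protein_display_name(c), c.protein_id, c.length,
                c.group, c.type_label, c.architecture,
                c.clp1p_length if c.clp1p_length is not None else "NA",
                f"{nm}/4", c.predicted_activity, c.n_isoforms,
            )) + "\n")
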
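"""Synthetic multi-species proteomes with planted family structure.

The generator emulates the situation observed in kinetoplastid-style
lineages: a duplicated kinase family whose members fall into two deep
groups (Clp1-like and Nol9/Grc3-like), with the Clp1 group further split
into cross-species "type" lineages distinguished by lineage-specific
C-terminal replacement domains, one lineage carrying an ablated Clasp
motif (kinase-dead), and the Nol9-like lineage carrying a truncated
(<130 aa) kinase domain.  Splicing-isoform records, a planted same-species
type duplicate, and composition-matched decoy proteins round out the
dataset.  Every emitted record has exactly one ground-truth row, and the
whole dataset is a deterministic function of (config, seed).

Sequence evolution is deliberately simple: domain templates are synthetic
(drawn from background residue frequencies, with canonical motif strings
embedded in the kinase template); lineages diverge by uniform random
substitution; motif sites are protected unless ablated; indels are kept
out of domains so true coordinates stay exact.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import CANONICAL_MOTIFS, GROUP_CLP1, GROUP_NOL9
from .msa import MultipleAlignment
from .records import ProteinRecord
from .scoring import AA_ORDER

#: offsets (0-based) of the four catalytic motifs inside the CLP1_P template
MOTIF_OFFSETS = {"WalkerA": 12, "WalkerB": 58, "Clasp": 108, "Lid": 148}

TEMPLATE_SPECS = {
    "CLP1_EN": 120,
    "CLP1_P": 170,
    "CLP1_EC": 130,
    "CLP1_EUC1": 145,
    "CLP1_EUC2": 150,
    "CLP1_EUC3": 140,
    "NOL9_EN": 100,
    "NOL9_EC": 120,
}

#: domains with profile seed alignments ("known"); the EUC domains are the
#: planted novel domains the discovery stage must find.
KNOWN_TEMPLATES = ("CLP1_EN", "CLP1_P", "CLP1_EC", "NOL9_EN", "NOL9_EC")

_BG = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
_BG = _BG / _BG.sum()

TEMPLATE_LIBRARY_SEED = 20230822


def generate_template_library() -> dict[str, str]:
    """Regenerate the synthetic domain-template library (the FASTA shipped in
    ``clp1kit/data`` was written by this function; templates are random
    draws from background frequencies, plus embedded canonical motifs)."""
    rng = np.random.default_rng(TEMPLATE_LIBRARY_SEED)
    out = {}
    for name, length in TEMPLATE_SPECS.items():
        seq = "".join(AA_ORDER[i] for i in rng.choice(20, size=length, p=_BG))
        if name == "CLP1_P":
            chars = list(seq)
            for motif, off in MOTIF_OFFSETS.items():
                canon = CANONICAL_MOTIFS[motif]
                chars[off:off + len(canon)] = canon
            seq = "".join(chars)
        out[name] = seq
    return out


def load_template_library() -> dict[str, str]:
    """Load the shipped synthetic domain-template FASTA."""
    ref = importlib.resources.files("clp1kit") / "data" / "domain_templates.fasta"
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in ref.read_text().splitlines():
        if line.startswith(">"):
            if name:
                out[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name:
        out[name] = "".join(chunks)
    return out


@dataclass(frozen=True)
class LineageConfig:
    """One planted protein lineage (a cross-species paralog 'type')."""

    name: str
    group: str
    architecture: tuple[str, ...]
    ablated_motifs: tuple[str, ...] = ()
    #: truncate the kinase template to this many residues (None = full)
    kinase_truncate_to: int | None = None
    duplication_prob: float = 0.0
    loss_prob: float = 0.0


DEFAULT_LINEAGES: tuple[LineageConfig, ...] = (
    LineageConfig("t1", GROUP_CLP1, ("CLP1_EN", "CLP1_P", "CLP1_EUC1"),
                  ablated_motifs=("Clasp",)),
    LineageConfig("t2", GROUP_CLP1, ("CLP1_EN", "CLP1_P", "CLP1_EUC2")),
    LineageConfig("t3", GROUP_CLP1, ("CLP1_EN", "CLP1_P", "CLP1_EUC3")),
    LineageConfig("nol9", GROUP_NOL9, ("NOL9_EN", "CLP1_P", "NOL9_EC"),
                  kinase_truncate_to=100),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 8
    lineages: tuple[LineageConfig, ...] = DEFAULT_LINEAGES
    #: divergence of each group ancestor from the family ancestor; the
    #: group duplication is the oldest event, well before the type
    #: duplications, so the kinase domain separates the groups cleanly
    group_divergence: float = 0.30
    #: divergence of each lineage ancestor from its group ancestor
    lineage_divergence: float = 0.18
    #: per-branch substitution probability on the species tree (depth 3 for 8 spp)
    substitution_rate: float = 0.04
    indel_rate: float = 0.0
    indel_mean_len: int = 3
    n_decoys: int = 3
    isoform_prob: float = 0.25
    #: (species, lineage) pairs that carry a same-species duplicate member
    planted_duplicates: tuple[tuple[str, str], ...] = (("sp08", "t3"),)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.group_divergence, self.lineage_divergence,
                  self.substitution_rate, self.indel_rate, self.isoform_prob):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not self.lineages:
            raise ValueError("need at least one lineage")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1:02d}" for i in range(self.n_species))


def ablate_motif(config: SimulationConfig, lineage_name: str, motif: str) -> SimulationConfig:
    """Return a config in which the given lineage's motif is ablated."""
    if motif not in MOTIF_OFFSETS:
        raise KeyError(f"unknown motif {motif!r}")
    new_lineages = []
    found = False
    for lin in config.lineages:
        if lin.name == lineage_name:
            found = True
            if motif not in lin.ablated_motifs:
                lin = replace(lin, ablated_motifs=lin.ablated_motifs + (motif,))
        new_lineages.append(lin)
    if not found:
        raise KeyError(f"unknown lineage {lineage_name!r}")
    return replace(config, lineages=tuple(new_lineages))


@dataclass
class SimulatedDataset:
    """Everything one pipeline run needs, plus the ground truth."""

    records: list[ProteinRecord]
    truth: pd.DataFrame
    species_tree_newick: str
    full_queries: list[ProteinRecord]
    domain_queries: list[ProteinRecord]
    seed_alignments: dict[str, MultipleAlignment]
    anchors: dict[str, str]  # record id -> group
    config: SimulationConfig

    def records_by_species(self) -> dict[str, list[ProteinRecord]]:
        out: dict[str, list[ProteinRecord]] = {s: [] for s in self.config.species_names}
        for r in self.records:
            out[r.species].append(r)
        return out


# ---------------------------------------------------------------------------
# sequence evolution helpers (index arrays over AA_ORDER)

def _to_idx(seq: str) -> np.ndarray:
    lut = {a: i for i, a in enumerate(AA_ORDER)}
    return np.array([lut[c] for c in seq], dtype=np.int64)


def _to_str(idx: np.ndarray) -> str:
    return "".join(AA_ORDER[i] for i in idx)


def _mutate(idx: np.ndarray, rate: float, rng: np.random.Generator,
            protected: np.ndarray | None = None) -> np.ndarray:
    out = idx.copy()
    hit = rng.random(len(idx)) < rate
    if protected is not None:
        hit &= ~protected
    n = int(hit.sum())
    if n:
        # substitute with a uniformly chosen *different* residue
        shift = rng.integers(1, 20, size=n)
        out[hit] = (out[hit] + shift) % 20
    return out


def _randomise_motif(idx: np.ndarray, start: int, canon: str,
                     rng: np.random.Generator) -> None:
    """Overwrite motif sites with residues guaranteed to break the pattern."""
    from .classify import DEFAULT_MOTIFS
    pattern = None
    for m in DEFAULT_MOTIFS:
        if CANONICAL_MOTIFS[m.name] == canon:
            pattern = m.pattern
            break
    for k, allowed in enumerate(pattern):
        forbidden = [i for i, a in enumerate(AA_ORDER) if a not in allowed]
        idx[start + k] = rng.choice(forbidden)


# ---------------------------------------------------------------------------
# species tree

def _balanced_topology(names: Sequence[str], rng: np.random.Generator):
    """Random balanced-ish binary topology (nested tuples of names)."""
    names = list(rng.permutation(np.array(names, dtype=object)))

    def build(sub):
        if len(sub) == 1:
            return sub[0]
        k = len(sub) // 2
        return (build(sub[:k]), build(sub[k:]))

    return build(names)


def _topology_newick(node, branch: float) -> str:
    if isinstance(node, str):
        return f"{node}:{branch:g}"
    return f"({_topology_newick(node[0], branch)},{_topology_newick(node[1], branch)}):{branch:g}"


def _evolve_down(node, idx: np.ndarray, rate: float, protected: np.ndarray,
                 rng: np.random.Generator, out: dict[str, np.ndarray]) -> None:
    child = _mutate(idx, rate, rng, protected)
    if isinstance(node, str):
        out[node] = child
    else:
        _evolve_down(node[0], child, rate, protected, rng, out)
        _evolve_down(node[1], child, rate, protected, rng, out)


# ---------------------------------------------------------------------------
# the generator

def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    templates = load_template_library()
    species = config.species_names
    taxa = {s: ("TaxonA" if i < config.n_species // 2 else "TaxonB")
            for i, s in enumerate(species)}

    # family ancestor -> group ancestors -> lineage ancestors (kinase core)
    family_p = _to_idx(templates["CLP1_P"])
    p_protected = np.zeros(len(family_p), dtype=bool)
    for motif, off in MOTIF_OFFSETS.items():
        p_protected[off:off + len(CANONICAL_MOTIFS[motif])] = True
    group_p: dict[str, np.ndarray] = {}
    for grp in (GROUP_CLP1, GROUP_NOL9):
        group_p[grp] = _mutate(family_p, config.group_divergence, rng, p_protected)

    topology = _balanced_topology(species, rng)
    root_branch = f":{config.substitution_rate:g}"
    species_tree = _topology_newick(topology, config.substitution_rate)
    if species_tree.endswith(root_branch):
        species_tree = species_tree[: -len(root_branch)]
    species_tree += ";"

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    anchors: dict[str, str] = {}
    lineage_ancestors: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}

    for lin in config.lineages:
        # assemble the lineage ancestor from domain templates + short linkers
        parts: list[tuple[str, np.ndarray, np.ndarray]] = []  # (name, idx, protected)
        lead = rng.integers(0, 5)
        if lead:
            parts.append(("linker", rng.choice(20, size=lead, p=_BG),
                          np.zeros(lead, dtype=bool)))
        for di, dom in enumerate(lin.architecture):
            if dom == "CLP1_P":
                core = _mutate(group_p[lin.group], config.lineage_divergence,
                               rng, p_protected)
                prot = p_protected.copy()
                for motif in lin.ablated_motifs:
                    off = MOTIF_OFFSETS[motif]
                    canon = CANONICAL_MOTIFS[motif]
                    _randomise_motif(core, off, canon, rng)
                    prot[off:off + len(canon)] = False
                if lin.kinase_truncate_to is not None:
                    core = core[:lin.kinase_truncate_to]
                    prot = prot[:lin.kinase_truncate_to]
                parts.append((dom, core, prot))
            else:
                dom_idx = _mutate(_to_idx(templates[dom]),
                                  config.lineage_divergence, rng)
                parts.append((dom, dom_idx, np.zeros(len(dom_idx), dtype=bool)))
            if di < len(lin.architecture) - 1:
                ll = rng.integers(3, 6)
                parts.append(("linker", rng.choice(20, size=ll, p=_BG),
                              np.zeros(ll, dtype=bool)))
        tail = rng.integers(0, 4)
        if tail:
            parts.append(("linker", rng.choice(20, size=tail, p=_BG),
                          np.zeros(tail, dtype=bool)))

        anc = np.concatenate([p[1] for p in parts])
        protected = np.concatenate([p[2] for p in parts])
        spans = []
        pos = 0
        for name, idx_part, _ in parts:
            if name != "linker":
                spans.append((name, pos + 1, pos + len(idx_part)))  # 1-based
            pos += len(idx_part)
        lineage_ancestors[lin.name] = (anc, protected, spans)

        leaves: dict[str, np.ndarray] = {}
        _evolve_down(topology, anc, config.substitution_rate, protected, rng, leaves)

        present_motifs = [m for m, off in MOTIF_OFFSETS.items()
                          if lin.kinase_truncate_to is None
                          or off + len(CANONICAL_MOTIFS[m]) <= lin.kinase_truncate_to]
        intact = [m for m in present_motifs if m not in lin.ablated_motifs]
        kinase_len = (lin.kinase_truncate_to if lin.kinase_truncate_to is not None
                      else len(family_p))
        active = (len(intact) == len(MOTIF_OFFSETS)) and kinase_len >= 130

        for sp in species:
            if rng.random() < lin.loss_prob:
                continue
            copies = [("", leaves[sp])]
            if (sp, lin.name) in config.planted_duplicates or rng.random() < lin.duplication_prob:
                dup = _mutate(leaves[sp], config.substitution_rate, rng, protected)
                copies.append(("d", dup))
            for tag, idx_seq in copies:
                rid = f"{sp}_{lin.name}{tag}"
                seq = _to_str(idx_seq)
                rec = ProteinRecord(id=rid, sequence=seq, species=sp,
                                    taxon=taxa[sp],
                                    description=f"{lin.name} family protein")
                records.append(rec)
                truth_rows.append({
                    "id": rid, "species": sp, "taxon": taxa[sp],
                    "lineage": lin.name, "group": lin.group,
                    "is_decoy": False, "is_isoform": False, "parent_id": "",
                    "activity": "active" if active else "inactive",
                    "architecture": "|".join(lin.architecture),
                    "domains": ";".join(f"{n}:{s}-{e}" for n, s, e in spans),
                    "motifs_present": ",".join(present_motifs),
                    "motifs_intact": ",".join(intact),
                })
                if rng.random() < config.isoform_prob:
                    frac = rng.uniform(0.6, 0.8)
                    iso_seq = seq[: max(int(len(seq) * frac), 50)]
                    iso_id = f"{rid}.iso1"
                    records.append(ProteinRecord(
                        id=iso_id, sequence=iso_seq, species=sp, taxon=taxa[sp],
                        description=f"{lin.name} family protein isoform X2",
                        is_isoform=True))
                    truth_rows.append({
                        "id": iso_id, "species": sp, "taxon": taxa[sp],
                        "lineage": lin.name, "group": lin.group,
                        "is_decoy": False, "is_isoform": True, "parent_id": rid,
                        "activity": "active" if active else "inactive",
                        "architecture": "", "domains": "",
                        "motifs_present": "", "motifs_intact": "",
                    })

    # anchors: one known member of each group in the first species
    for lin in config.lineages:
        candidate = f"{species[0]}_{lin.name}"
        if lin.group not in anchors.values() and any(r.id == candidate for r in records):
            anchors[candidate] = lin.group

    # decoys: composition-preserving shuffles of the concatenated templates
    pool = _to_idx("".join(templates.values()))
    for sp in species:
        for d in range(config.n_decoys):
            L = int(rng.integers(300, 701))
            shuffled = rng.permutation(pool)
            seq = _to_str(shuffled[:L])
            rid = f"{sp}_decoy{d + 1}"
            records.append(ProteinRecord(id=rid, sequence=seq, species=sp,
                                         taxon=taxa[sp],
                                         description="hypothetical protein"))
            truth_rows.append({
                "id": rid, "species": sp, "taxon": taxa[sp],
                "lineage": "", "group": "", "is_decoy": True,
                "is_isoform": False, "parent_id": "", "activity": "",
                "architecture": "", "domains": "",
                "motifs_present": "", "motifs_intact": "",
            })

    # queries: the active Clp1-type ancestor and the Nol9-like ancestor,
    # full-length plus their kinase-domain regions
    full_queries, domain_queries = [], []
    for lin_name in _query_lineages(config):
        anc, _prot, spans = lineage_ancestors[lin_name]
        qid = f"query_{lin_name}"
        full_queries.append(ProteinRecord(id=qid, sequence=_to_str(anc)))
        for name, s, e in spans:
            if name == "CLP1_P":
                domain_queries.append(ProteinRecord(
                    id=f"{qid}_P", sequence=_to_str(anc[s - 1:e])))

    seed_alignments = {
        t: _seed_alignment(t, templates[t], rng)
        for t in KNOWN_TEMPLATES
    }

    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        records=records, truth=truth, species_tree_newick=species_tree,
        full_queries=full_queries, domain_queries=domain_queries,
        seed_alignments=seed_alignments, anchors=anchors, config=config,
    )


def _query_lineages(config: SimulationConfig) -> list[str]:
    """One query lineage per group: the first lineage of each group."""
    seen: dict[str, str] = {}
    for lin in config.lineages:
        if lin.group not in seen:
            seen[lin.group] = lin.name
    return list(seen.values())


def _seed_alignment(name: str, template: str, rng: np.random.Generator,
                    n_rows: int = 6, divergence: float = 0.08) -> MultipleAlignment:
    """Gap-free seed alignment of mutated template copies (motifs protected)."""
    idx = _to_idx(template)
    protected = np.zeros(len(idx), dtype=bool)
    if name == "CLP1_P":
        for motif, off in MOTIF_OFFSETS.items():
            protected[off:off + len(CANONICAL_MOTIFS[motif])] = True
    rows = []
    for i in range(n_rows):
        rows.append(_to_str(_mutate(idx, divergence, rng, protected)))
    ids = tuple(f"{name}_seed{i + 1}" for i in range(n_rows))
    return MultipleAlignment(ids, tuple(rows))


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Persist per-species FASTA files, the truth TSV, and the species tree."""
    from .records import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, recs in ds.records_by_species().items():
        write_fasta(recs, outdir / f"{sp}.fasta")
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "species_tree.nwk").write_text(ds.species_tree_newick + "\n")
    write_fasta(ds.full_queries, outdir / "queries_full.fasta")
    write_fasta(ds.domain_queries, outdir / "queries_domain.fasta")
    with open(outdir / "metadata.tsv", "w") as fh:
        fh.write("id\tspecies\ttaxon\n")
        for r in ds.records:
            fh.write(f"{r.id}\t{r.species}\t{r.taxon}\n")
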
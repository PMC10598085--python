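"""End-to-end orchestration: search -> inventory -> clustering -> domains ->
kinase-domain tree -> classification -> reports.

Stage order follows the family-survey workflow: candidate members are found
by dual-query local-alignment search, counted per species with isoforms
collapsed, reduced by identity clustering (with reference genes re-added),
annotated with known-domain profiles and novel-domain discovery, placed on
a midpoint-rooted tree of their kinase domains, split into the two family
groups by anchor membership, typed within groups, and scored for the four
catalytic motifs to predict kinase activity.

All artifacts are plain text (TSV / FASTA / newick / JSON manifest) and a
re-run with the same inputs and config reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classify as _classify
from .classify import (DEFAULT_MOTIFS, FamilyCall, GROUP_CLP1, MotifModel,
                       TypeAssignment, UNKNOWN, assign_types, identity_matrix,
                       predict_activity, scan_motifs, split_groups,
                       write_calls_tsv, write_matrix_tsv)
from .cluster import Cluster, greedy_cluster, representative_set
from .domains import (Architecture, DomainHit, DomainProfile, NovelDomain,
                      Segment, assemble_architecture, build_profile,
                      discover_novel_domains, scan_profiles,
                      unannotated_segments, write_domain_hits_tsv)
from .msa import MultipleAlignment, progressive_msa
from .records import ProteinRecord, collapse_isoforms, gene_key
from .search import (InventoryRow, InventorySummary, LocalHit, SearchParams,
                     build_inventory, dual_query_search, write_hits_tsv,
                     write_inventory_tsv)
from .tree import (bootstrap_support, midpoint_root, tree_from_alignment,
                   write_newick, newick_string)

KINASE_DOMAIN = "CLP1_P"


@dataclass(frozen=True)
class PipelineConfig:
    search: SearchParams = field(default_factory=SearchParams)
    cluster_threshold: float = 0.70
    #: re-add every inventory gene after clustering (reference-organism set)
    readd_all_genes: bool = True
    domain_evalue_max: float = 1e-3
    novel_evalue_max: float = 1e-4
    novel_coverage_min: float = 0.30
    novel_min_members: int = 3
    novel_min_species: int = 3
    segment_min_len: int = 50
    bootstrap_reps: int = 0
    kimura_distances: bool = True
    motif_models: tuple[MotifModel, ...] = DEFAULT_MOTIFS
    #: species whose members feed the round-robin identity matrix (default:
    #: the species of the first anchor record)
    matrix_species: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.cluster_threshold <= 1):
            raise ValueError("cluster_threshold must be in (0, 1]")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")


@dataclass
class PipelineResult:
    hits: list[LocalHit]
    inventory: list[InventoryRow]
    inventory_summary: InventorySummary
    clusters: list[Cluster]
    representatives: list[ProteinRecord]
    profiles: list[DomainProfile]
    novel_domains: list[NovelDomain]
    architectures: dict[str, Architecture]
    kinase_alignment: MultipleAlignment | None
    tree: object | None  # rooted skbio TreeNode
    groups: dict[str, str]
    type_assignments: dict[str, TypeAssignment]
    calls: list[FamilyCall]
    matrix: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    records: Sequence[ProteinRecord],
    full_queries: Sequence[ProteinRecord],
    domain_queries: Sequence[ProteinRecord],
    seed_alignments: Mapping[str, MultipleAlignment],
    anchors: Mapping[str, str],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    config.validate()
    manifest: dict = {
        "stages": [],
        "seed": config.seed,
        "parameters": _jsonable_config(config),
        "input_sha256": _input_hash(records),
        "n_input_records": len(records),
    }
    by_id = {r.id: r for r in records}

    def stage(name: str) -> None:
        manifest["stages"].append(name)

    # 1. identification
    hits = dual_query_search(full_queries, domain_queries, records, config.search)
    stage("search")

    # 2. inventory (isoforms collapsed for gene counts)
    inventory, summary = build_inventory(hits, records)
    stage("inventory")

    detected = [by_id[h.target_id] for h in hits]
    genes = collapse_isoforms(detected)
    n_isoforms = {
        g.id: sum(1 for d in detected
                  if gene_key(d.id) == gene_key(g.id) and d.is_isoform)
        for g in genes
    }

    # 3. clustering + representative selection
    clusters = greedy_cluster(genes, config.cluster_threshold, config.search.scheme)
    readd = [g.id for g in genes] if config.readd_all_genes else list(anchors)
    reps = representative_set(clusters, genes, anchors=[a for a in readd if a in by_id])
    reps = sorted(reps, key=lambda r: r.id)
    stage("cluster")

    # 4. domain annotation
    profiles = [build_profile(aln, name)
                for name, aln in sorted(seed_alignments.items())]
    profile_hits: dict[str, list[DomainHit]] = {}
    segments: list[Segment] = []
    for r in reps:
        ph = scan_profiles(r, profiles, evalue_max=config.domain_evalue_max)
        profile_hits[r.id] = ph
        for (s, e) in unannotated_segments(r, ph, min_len=config.segment_min_len):
            segments.append(Segment(r.id, r.species, s, e, r.sequence[s - 1:e]))
    novel = discover_novel_domains(
        segments,
        evalue_max=config.novel_evalue_max,
        coverage_min=config.novel_coverage_min,
        min_members=config.novel_min_members,
        min_species=config.novel_min_species,
    )
    novel_by_prot: dict[str, list[DomainHit]] = {}
    for nd in novel:
        for h in nd.members:
            novel_by_prot.setdefault(h.protein_id, []).append(h)
    architectures = {
        r.id: assemble_architecture(r, profile_hits[r.id],
                                    novel_by_prot.get(r.id, []))
        for r in reps
    }
    stage("domains")

    # 5. kinase-domain alignment and midpoint-rooted tree
    p_spans: dict[str, str] = {}
    for r in reps:
        span = architectures[r.id].span_of(KINASE_DOMAIN)
        if span:
            p_spans[r.id] = r.sequence[span[0] - 1:span[1]]
    kinase_alignment = None
    rooted = None
    groups: dict[str, str] = {}
    type_assignments: dict[str, TypeAssignment] = {}
    if len(p_spans) >= 3:
        kinase_alignment = progressive_msa(
            [ProteinRecord(id=k, sequence=v) for k, v in sorted(p_spans.items())],
            config.search.scheme)
        if config.bootstrap_reps > 0:
            tree = bootstrap_support(kinase_alignment, config.bootstrap_reps,
                                     seed=config.seed,
                                     kimura=config.kimura_distances)
        else:
            tree = tree_from_alignment(kinase_alignment,
                                       kimura=config.kimura_distances)
        rooted = midpoint_root(tree)
        stage("tree")

        # 6. classification
        tree_anchors = {a: g for a, g in anchors.items() if a in p_spans}
        groups = split_groups(rooted, tree_anchors)
        species_of = {r.id: r.species for r in reps}
        arch_strings = {rid: a.string for rid, a in architectures.items()}
        for grp in sorted(set(groups.values()) - {UNKNOWN}):
            members = sorted(i for i, g in groups.items() if g == grp)
            if len(members) >= 2:
                type_assignments[grp] = assign_types(
                    members, species_of, rooted, arch_strings)
        stage("classify")

    calls: list[FamilyCall] = []
    for r in reps:
        grp = groups.get(r.id, UNKNOWN)
        ta = type_assignments.get(grp)
        label = ta.labels.get(r.id, "") if ta else ""
        flagged = bool(ta and r.id in ta.flagged_duplicates)
        span_seq = p_spans.get(r.id)
        report = scan_motifs(span_seq or "", config.motif_models)
        calls.append(FamilyCall(
            protein_id=r.id, species=r.species, group=grp, type_label=label,
            architecture=architectures[r.id].string,
            motif_report=report,
            clp1p_length=len(span_seq) if span_seq else None,
            predicted_activity=predict_activity(
                report, len(span_seq) if span_seq else None),
            duplicate_in_clade=flagged,
            length=len(r.sequence),
            n_isoforms=n_isoforms.get(r.id, 0),
        ))

    # 7. round-robin identity matrix for the focal species
    matrix = None
    focal = config.matrix_species
    if focal is None and anchors:
        focal = by_id[sorted(anchors)[0]].species if sorted(anchors)[0] in by_id else None
    if focal is not None:
        members = [r for r in reps if r.species == focal]
        if len(members) >= 2:
            matrix = identity_matrix(members, config.search)
    stage("matrix")

    result = PipelineResult(
        hits=hits, inventory=inventory, inventory_summary=summary,
        clusters=clusters, representatives=reps, profiles=profiles,
        novel_domains=novel, architectures=architectures,
        kinase_alignment=kinase_alignment, tree=rooted, groups=groups,
        type_assignments=type_assignments, calls=calls, matrix=matrix,
        manifest=manifest,
    )
    if outdir is not None:
        persist_result(result, outdir)
    return result


def run_pipeline_on_dataset(dataset, config: PipelineConfig | None = None,
                            outdir: str | Path | None = None) -> PipelineResult:
    """Convenience wrapper for a :class:`~clp1kit.simulate.SimulatedDataset`."""
    return run_pipeline(
        records=dataset.records,
        full_queries=dataset.full_queries,
        domain_queries=dataset.domain_queries,
        seed_alignments=dataset.seed_alignments,
        anchors=dataset.anchors,
        config=config,
        outdir=outdir,
    )


def persist_result(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_hits_tsv(result.hits, outdir / "hits.tsv")
    write_inventory_tsv(result.inventory, outdir / "inventory.tsv")
    all_hits = [h for a in result.architectures.values() for h in a.hits]
    write_domain_hits_tsv(all_hits, outdir / "domains.tsv")
    with open(outdir / "architectures.tsv", "w") as fh:
        fh.write("protein_id\tarchitecture\n")
        for rid in sorted(result.architectures):
            fh.write(f"{rid}\t{result.architectures[rid].string}\n")
    if result.tree is not None:
        write_newick(result.tree, outdir / "kinase_tree.nwk")
    write_calls_tsv(result.calls, outdir / "family_calls.tsv")
    if result.matrix is not None:
        write_matrix_tsv(result.matrix, outdir / "identity_matrix.tsv")
    manifest = dict(result.manifest)
    manifest["outputs_sha256"] = _dir_hash(outdir)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _input_hash(records: Sequence[ProteinRecord]) -> str:
    h = hashlib.sha256()
    for r in sorted(records, key=lambda r: r.id):
        h.update(r.id.encode())
        h.update(r.sequence.encode())
    return h.hexdigest()


def _dir_hash(outdir: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.nwk")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _jsonable_config(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(x) for x in obj]
        if hasattr(obj, "tolist"):
            return "matrix"
        return obj

    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name == "search":
            out[f.name] = {
                "evalue_max": v.evalue_max, "coverage_min": v.coverage_min,
                "scheme": v.scheme.name, "seed_word_length": v.seed_word_length,
                "exact_cell_cutoff": v.exact_cell_cutoff,
            }
        elif f.name == "motif_models":
            out[f.name] = [m.name for m in v]
        else:
            out[f.name] = convert(v)
    return out
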
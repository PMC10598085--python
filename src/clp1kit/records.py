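"""Protein sequence records and FASTA / metadata I/O.

The pipeline operates on amino-acid sequences tagged with species and
taxon metadata, mirroring how RefSeq per-species proteomes are organised.
Records flagged as splicing isoforms are kept through the search stage and
collapsed (longest representative wins) when genes are counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 canonical residues plus X (unknown); everything else is rejected.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = frozenset(CANONICAL + "X")

_ILLEGAL_RE = re.compile(rf"[^{CANONICAL}X]")


class FastaParseError(ValueError):
    """Malformed FASTA input (reported with the offending line or id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its provenance.

    Attributes
    ----------
    id:
        Accession-like identifier, unique within a dataset.
    species, taxon:
        Organism name and higher taxonomic group (may be empty when no
        metadata table was supplied).
    sequence:
        Upper-case amino acids; 20 canonical letters plus ``X``.
    description:
        Free text after the id on the FASTA header line.
    is_isoform:
        True when the description carries the isoform marker (RefSeq-style
        "isoform" annotations of splice variants).
    """

    id: str
    sequence: str
    species: str = ""
    taxon: str = ""
    description: str = ""
    is_isoform: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = _ILLEGAL_RE.search(self.sequence)
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue letter {bad.group()!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_metadata(self, species: str, taxon: str) -> "ProteinRecord":
        return replace(self, species=species, taxon=taxon)


def read_fasta(
    path: str | Path,
    metadata: Mapping[str, tuple[str, str]] | None = None,
    isoform_marker: str = "isoform",
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Parameters
    ----------
    metadata:
        Optional mapping ``id -> (species, taxon)`` (see
        :func:`read_metadata_tsv`).
    isoform_marker:
        Case-insensitive substring of the description that flags a splicing
        isoform record.
    """
    path = Path(path)
    marker = isoform_marker.lower()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython names the offending line
        raise FastaParseError(f"{path}: {exc}") from exc
    if not parsed and path.stat().st_size > 0:
        raise FastaParseError(f"{path}: no FASTA entries found (missing '>' header?)")
    for sr in parsed:
        rid = sr.id
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        desc = sr.description[len(sr.id):].strip() if sr.description.startswith(sr.id) else sr.description
        seq = str(sr.seq).upper()
        species, taxon = ("", "")
        if metadata and rid in metadata:
            species, taxon = metadata[rid]
        try:
            rec = ProteinRecord(
                id=rid,
                sequence=seq,
                species=species,
                taxon=taxon,
                description=desc,
                is_isoform=marker in desc.lower(),
            )
        except ValueError as exc:
            raise FastaParseError(str(exc)) from exc
        records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA; round-trips ids and sequences byte-identically."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_metadata_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a 3-column TSV (id, species, taxon) into a mapping."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "species", "taxon"]:
            raise ValueError(f"{path}: expected columns id, species, taxon")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = (fields[1], fields[2])
    return out


def collapse_isoforms(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Collapse isoform sets to one representative per gene (the longest).

    Isoform records are grouped with their sibling non-isoform record by
    (species, base gene key); here the gene key is the record id stripped of a
    trailing ``.isoN`` tag when present, which is how the simulator (and the
    importers) mark isoform records.  Within each group the longest sequence
    wins; ties break on lexicographically smallest id.
    """
    groups: dict[str, list[ProteinRecord]] = {}
    for r in records:
        groups.setdefault(gene_key(r.id), []).append(r)
    reps = []
    for members in groups.values():
        members = sorted(members, key=lambda r: (-len(r.sequence), r.id))
        reps.append(members[0])
    reps.sort(key=lambda r: r.id)
    return reps


def gene_key(record_id: str) -> str:
    """Strip a trailing ``.isoN`` isoform tag from a record id."""
    return re.sub(r"\.iso\d+$", "", record_id)
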
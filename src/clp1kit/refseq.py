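"""Fetching reference protein records from NCBI (network required).

Used to pull the published T. brucei family members (the four RefSeq
proteins behind the identity/similarity and molecular-weight table) so the
matrix and mass computations can be checked against printed values.  A
local FASTA cache is honoured when present so the check can run offline
once the sequences have been obtained.
"""

from __future__ import annotations

import socket
from pathlib import Path
from typing import Sequence

from .records import ProteinRecord, read_fasta

TBRUCEI_TABLE2_ACCESSIONS = (
    "XP_843821.1",  # Tb-Clp1-t1, 441 aa
    "XP_845487.1",  # Tb-Clp1-t2, 423 aa
    "XP_844561.1",  # Tb-Clp1-t3, 512 aa
    "XP_846962.1",  # Tb-Nol9/Grc3, 1034 aa
)


def fetch_refseq_proteins(
    accessions: Sequence[str],
    cache: str | Path | None = None,
    timeout: float = 15.0,
    email: str = "clp1kit@example.org",
) -> list[ProteinRecord]:
    """Fetch protein records by RefSeq accession via NCBI E-utilities.

    If ``cache`` names an existing FASTA file, records are read from it
    instead (ids matched on the accession before the first space).
    """
    if cache is not None and Path(cache).exists():
        recs = {r.id.split()[0]: r for r in read_fasta(cache)}
        return [recs[a] for a in accessions]
    from Bio import Entrez, SeqIO

    Entrez.email = email
    old_timeout = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        handle = Entrez.efetch(db="protein", id=",".join(accessions),
                               rettype="fasta", retmode="text")
        parsed = {r.id: str(r.seq) for r in SeqIO.parse(handle, "fasta")}
    finally:
        socket.setdefaulttimeout(old_timeout)
    return [ProteinRecord(id=a, sequence=parsed[a]) for a in accessions]
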
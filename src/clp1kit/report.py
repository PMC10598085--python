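"""Publication-style summary tables.

Formats the pipeline's results the way family surveys present them: a
per-protein classification table, a round-robin "identity (similarity)"
matrix with "N/D" for undetected pairs, a per-taxon histogram of family
gene counts, and a "mean +- SD genes per species" summary line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .classify import write_calls_tsv, write_matrix_tsv
from .pipeline import PipelineResult
from .records import ProteinRecord


def gene_count_histogram(
    result: PipelineResult, records: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Rows (taxon, n_genes, n_species): how many species of each taxon carry
    each family gene count (species with zero members included)."""
    taxon_of = {}
    for r in records:
        taxon_of.setdefault(r.species, r.taxon)
    rows = []
    for inv in result.inventory:
        rows.append({"taxon": taxon_of.get(inv.species, ""),
                     "species": inv.species, "n_genes": inv.n_genes})
    df = pd.DataFrame(rows)
    hist = (df.groupby(["taxon", "n_genes"]).size()
            .reset_index(name="n_species")
            .sort_values(["taxon", "n_genes"]).reset_index(drop=True))
    return hist


def summary_line(result: PipelineResult) -> str:
    s = result.inventory_summary
    if not s.defined:
        return "no family members detected; mean genes/species undefined"
    return (f"{s.mean_genes_per_species:.1f} ± {s.sd_genes_per_species:.1f} "
            f"family genes per species over {s.n_species_with_members} species "
            f"with at least one member")


def report_tables(
    result: PipelineResult,
    records: Sequence[ProteinRecord],
    outdir: str | Path,
) -> None:
    """Write the classification table, identity matrix, per-taxon histogram,
    and plain-text summary.  Empty results still produce headed tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_calls_tsv(result.calls, outdir / "table_family.tsv")
    if result.matrix is not None:
        write_matrix_tsv(result.matrix, outdir / "table_matrix.tsv")
    else:
        (outdir / "table_matrix.tsv").write_text("query\n")
    hist = gene_count_histogram(result, records)
    hist.to_csv(outdir / "table_gene_counts.tsv", sep="\t", index=False)
    (outdir / "summary.txt").write_text(summary_line(result) + "\n")
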
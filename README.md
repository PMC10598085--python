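# clp1kit

Comparative-genomics analysis of the **Clp1/Nol9/Grc3 polynucleotide-kinase
(PNK) protein family**, packaged as a tested, fully reproducible pipeline
that runs end-to-end on synthetic proteomes with planted ground truth.

Eukaryotic Clp1-family proteins split into two ancient paralogous groups —
Clp1 (tRNA/mRNA 5′-end kinases) and Nol9/Grc3 (pre-rRNA kinases) — built
around a central P-loop kinase domain (Clp1_P) whose activity requires four
motifs (Walker A, Walker B, Clasp, Lid) and a domain length of at least
130 aa.  In some protist lineages the family expanded into cross-species
paralog "types" distinguished by lineage-specific C-terminal replacement
domains, only some of which remain catalytically active.  `clp1kit`
reconstructs all of this from proteome FASTA files:

- seeded local-alignment homolog search with Karlin–Altschul statistics
  (E = K·m·n·e^(−λS); BLOSUM62, gap 11/1; E ≤ 1e−4, query coverage ≥ 30%),
  dual full-length + kinase-domain queries merged without duplication;
- per-species inventories with splicing isoforms collapsed to the longest
  representative (mean ± SD genes/species);
- greedy 70%-identity clustering with reference genes re-added;
- PSSM domain annotation (E ≤ 1e−3, Gumbel null) plus de-novo discovery of
  novel conserved domains in unannotated regions (single-linkage
  components, ≥ 3 members from ≥ 3 species, mean ± SD lengths);
- progressive kinase-domain alignment, Kimura-corrected neighbor-joining
  trees with bootstrap supports, midpoint rooting;
- group splitting at the root, type (t1, t2, …) and letter-suffix
  assignment, catalytic-motif scanning, and activity prediction
  (active ⇔ all four motifs present ∧ Clp1_P ≥ 130 aa);
- publication-style tables, including the round-robin
  "identity (similarity)" matrix with "N/D" cells.

The synthetic-data generator (`clp1kit.simulate`) is a first-class module:
it plants a known family structure — three Clp1 types (one Clasp-ablated),
a short-kinase Nol9-like lineage, a same-species type duplicate, isoforms,
and composition-matched decoys — and emits machine-readable ground truth so
every stage can be scored (`clp1kit.evaluate`).

## Worked example

The numbered scripts under `analysis/` run the study step by step and
write their tables under `results/`.  On the default dataset (seed 1):

```bash
$ python analysis/01_simulate.py
  70 records over 8 species: 46 family (incl. 13 isoforms), 24 decoys

$ python analysis/04_domains.py
architectures:
    9  CLP1_EN|CLP1_P|NDOM1
    8  NOL9_EN|CLP1_P|NOL9_EC
    8  CLP1_EN|CLP1_P|NDOM2
    8  CLP1_EN|CLP1_P|NDOM3
novel domains:
  NDOM1: 9 members in 8 species, 146.0 ± 0.0 aa
  NDOM2: 8 members in 8 species, 151.0 ± 0.0 aa
  NDOM3: 8 members in 8 species, 154.0 ± 0.0 aa

$ python analysis/05_classify.py
groups: {'Nol9/Grc3': 8, 'Clp1': 25}
  Clp1       t1  active    x9
  Clp1       t2  inactive  x8
  Clp1       t3  active    x8
  Nol9/Grc3  -   inactive  x8
flagged same-species duplicates in a type clade: ['sp08_t3', 'sp08_t3d']
```

Reading this output: the 46 planted family records were all detected and
no decoy slipped through; after isoform collapse each species carries four
family genes (`02` prints `4.1 ± 0.3` genes/species).  The domain stage
recovered the known three-domain architectures and discovered exactly the
three planted C-terminal replacement domains (planted lengths 140/145/150
aa; the few extra residues are the short inter-domain linkers).  The
kinase-domain tree separated the Clp1 and Nol9/Grc3 groups, the three
Clp1 types formed clean cross-species clades (type numbers are ordered by
clade size, so `t1` here is the 9-member clade containing the planted
duplicate, which is flagged), and activity calls follow the motif/length
rule: the Clasp-ablated lineage and the short-kinase Nol9-like lineage are
inactive, the other two types active.  `analysis/06_report.py` scores
every stage against the ground truth (all metrics 1.0 on this dataset).

The library surface mirrors the scripts, e.g.:

```python
from clp1kit import (SimulationConfig, simulate_dataset,
                     run_pipeline_on_dataset, expected_recovery_report)

ds = simulate_dataset(SimulationConfig(seed=1))
res = run_pipeline_on_dataset(ds, outdir="results/pipeline")
print(expected_recovery_report(ds.truth, res))
```

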
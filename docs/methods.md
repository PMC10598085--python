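# Methods

`clp1kit` implements a complete comparative-genomics survey of the
Clp1/Nol9/Grc3 polynucleotide-kinase (PNK) protein family, exercised
end-to-end on synthetic proteomes with planted ground truth.  This note
documents the models and procedures, the parameters that matter, what the
simulator does and does not emulate, and the numerical choices made where
the design was open.

## The analysis

Eukaryotic Clp1-family proteins fall into two paralogous groups that arose
from an ancient gene duplication: the Clp1 group (tRNA/mRNA 5′-end
kinases) and the Nol9/Grc3 group (pre-rRNA processing kinases).  Both are
built around a central P-loop kinase domain (Clp1_P) flanked by
group-specific N- and C-terminal domains; in some protist lineages the
canonical C-terminal domain has been replaced by lineage-specific domains,
and the resulting cross-species paralog lineages ("types" t1, t2, t3)
differ in whether they retain PNK activity.  The pipeline reconstructs
this picture from proteomes alone:

1. **Homolog search** (`search`): every proteome sequence is compared with
   both full-length and kinase-domain-only query sequences by gapped local
   alignment (BLOSUM62, gap open 11 / extend 1).  Hits need E ≤ 1e-4 and
   query coverage ≥ 30%; the two query classes are merged without
   duplication, keeping each target's best hit.  E-values use
   Karlin–Altschul statistics E = K·m·n·e^(−λS) with the standard gapped
   BLOSUM62/11/1 constants λ = 0.267, K = 0.041 (no composition-based or
   effective-length corrections — simple and reproducible).  The alignment
   engine is exact Smith–Waterman below 250,000 DP cells and a word-seeded
   window heuristic above (exact DP inside a band around the best seed
   diagonal); an acceptance check verifies the engine against an
   independent exhaustive DP on hundreds of pairs.
2. **Inventory** (`inventory`): per-species counts of family records and of
   genes, collapsing splicing-isoform records to the longest
   representative; the summary line reports mean ± population SD genes per
   species over species with ≥ 1 member.
3. **Clustering** (`cluster`): greedy length-sorted clustering at 70%
   identity (identical positions of a global alignment divided by the
   shorter length, mirroring CD-HIT semantics).  Reference genes are
   re-added after clustering, as family surveys do for their
   representative-organism sets.
4. **Domain annotation** (`domains`): known domains are located with
   log-odds PSSMs built from seed alignments (background-proportional
   pseudocounts totalling 20 counts; columns > 50% gap excluded).  A
   profile's best ungapped local placement is found by a maximum-subarray
   scan over all diagonals, so truncated domain instances report their
   true, shorter extent; placements matching ≥ 90% of the model's columns
   are reported glocally (full model span), and placements under 50% are
   discarded as fragments.  Significance comes from a Gumbel null fitted
   to best-placement scores on 200 sequences drawn from the seed
   alignment's own residue composition (length 400; the tail probability
   scales linearly with the scanned length); hits need E ≤ 1e-3.
   Overlaps are resolved best-score-first; a lower-scoring hit loses at
   most half of itself to trimming before being dropped.
5. **Novel-domain discovery**: unannotated regions ≥ 50 aa are compared
   all-against-all with the same local search (E ≤ 1e-4, coverage ≥ 30%);
   single-linkage components with ≥ 3 members from ≥ 3 species become
   novel domains (NDOM1, NDOM2, … by decreasing size).  Member boundaries
   are refined to the component-alignment core (columns covered by ≥ 50%
   of members), and each domain reports mean ± SD length and species
   spread.
6. **Phylogeny** (`tree`): the kinase-domain spans of all representatives
   are aligned by progressive profile–profile alignment (k-mer-distance
   average-linkage guide tree; affine-gap Gotoh DP with free terminal
   gaps; for two sequences this equals the optimal global pairwise
   alignment).  Distances are Kimura-corrected fraction differences
   (d = −ln(1 − p − 0.2p²), computed over columns where both rows have
   residues; saturated values capped at 10).  Trees come from
   neighbor joining implemented directly, with negative branch-length
   estimates clamped to zero and the deficit moved to the sibling edge, so
   exactly additive inputs are reproduced to 1e-9.  Support values are a
   nonparametric column-resampling bootstrap (seeded; support = % of
   replicate trees containing each bipartition).  Trees are midpoint-rooted
   (root halfway along the longest leaf-to-leaf path).
7. **Classification** (`classify`): the two subtrees under the midpoint
   root are labelled Clp1 vs Nol9/Grc3 by majority membership of anchor
   proteins of known group; a tie, or both groups' anchors majority in one
   subtree, is an explicit classification-failure error.  Within a group,
   maximal clades with members from ≥ 2 species, at most one member per
   species (a single extra same-species duplicate is tolerated and
   flagged), and a shared domain-architecture signature unique among such
   clades become types t1…tn, numbered by decreasing clade size (ties by
   alphabetically first member id).  Remaining same-species co-occurring
   members get letter suffixes -a, -b, -c in input order; a species' sole
   group member keeps its bare name.  Type numbering is by clade size, so
   labels are stable but not semantically anchored (the lineage called t1
   in one run may be called t2 in another ordering).
8. **Motifs and activity**: four catalytic-site motifs (Walker A, Walker B,
   Clasp, Lid) are scanned left-to-right within the kinase-domain span,
   each at its minimum-mismatch position after the previous motif's end.
   Default patterns: Walker A `[AG]-x(4)-G-K-[ST]`; Walker B four
   hydrophobics then `[DE]-[DE]`; the Clasp and Lid patterns are synthetic
   stand-ins consistent with the simulator's planted consensus and are
   user-overridable, since published consensus strings for them live in
   supplementary material not bundled here.  A protein is predicted
   **active** iff all four motifs match *and* its kinase domain is ≥ 130 aa
   (the two lines of evidence are combined conjunctively); **inactive**
   otherwise; **unknown** when no kinase domain was located.
9. **Reporting** (`report`): a per-protein classification table, a
   round-robin "identity (similarity)" matrix (integer percentages of the
   best local alignment, alignment-length denominator including gap
   columns; "N/D" when no hit passes the search thresholds; an en dash on
   the diagonal), a per-taxon gene-count histogram, and the mean ± SD
   summary line.  All outputs are plain TSV/FASTA/newick plus a JSON run
   manifest; reruns with the same inputs are byte-identical.

Identity and similarity are defined per alignment column: identity =
identical columns / alignment length, similarity additionally counts
columns with a positive BLOSUM62 score ("chemically similar" is
operationalised as substitution score > 0).  Both are rounded to integers
for table output.  Molecular masses are average (not monoisotopic) residue
masses plus one water, reported in kDa; X and empty sequences are
rejected.  Alignment-column conservation uses the 12-rank physicochemical
scheme: rank 11 (`*`) for identical gap-free columns, rank 10 (`+`) for
gap-free columns whose residues agree on every one of the ten
physicochemical properties (hydrophobic, aliphatic, aromatic, polar,
charged, positive, negative, small, tiny, proline), otherwise the number
of properties uniformly present or uniformly absent, capped at 9 whenever
the column contains a gap.  All coordinates are 1-based inclusive
throughout.

## The synthetic-data generator

`simulate_dataset` emulates the study conditions of a protist-style family
survey: 8 species, three Clp1-type lineages with distinct C-terminal
replacement domains (the planted "novel" domains), and one Nol9/Grc3-like
lineage.  Lineage t1 carries an ablated Clasp motif (kinase-dead); the
Nol9-like lineage carries a kinase domain truncated to 100 aa (< 130,
hence inactive, with the Clasp and Lid sites absent entirely); t2 and t3
are fully active.  One species carries a planted same-species duplicate of
one type, mirroring the known single-duplicate exception.  Each gene may
emit a truncated splicing-isoform record (probability 0.25, marked
"isoform" in the description); each species also receives three decoys —
composition-preserving shuffles of the concatenated domain templates, the
hardest realistic negatives.

Sequences descend from a family ancestor through a two-level hierarchy:
group ancestors diverge 30% from the family ancestor (the group
duplication is the oldest event, so the kinase domain separates the groups
cleanly), lineage ancestors diverge a further 18% from their group
ancestor, and species evolve down a random balanced topology at 4%
substitutions per branch (leaf divergence from the lineage ancestor
≈ 12%, within-lineage pairwise divergence ≈ 20–24%).  Substitutions are
uniform over the 19 alternative residues; catalytic-motif sites are
protected unless ablated, and ablated sites are randomised to residues
outside the motif's residue classes.  Indels are excluded from domains (and
off by default everywhere) so planted coordinates stay exact; inter-domain
linkers are short (3–5 aa) with 0–4 aa terminal tails.  Domain templates
are synthetic draws from background residue frequencies (shipped as FASTA
in `clp1kit/data/`, regenerable with `generate_template_library`), so the
test data contain no copied database sequences.  Everything is a
deterministic function of (config, seed).

What this does **not** emulate — and hence what passing tests do not show
about real data: indel-rich evolution and alignment ambiguity,
heterogeneous rates across sites and lineages, compositional drift,
fragmentary gene models, database annotation noise beyond the "isoform"
token, and profile models trained on distant homologs.  Real surveys also
face database-scale multiple-testing regimes that the fixed
Karlin–Altschul constants only approximate.

## Problem sizes and determinism

The default study dataset is ~70 records (46 family records including
isoforms, 24 decoys) of 300–700 aa over 8 species; a full pipeline run
takes about two seconds, and the acceptance script replicates it over ten
seeds plus the oracle-equivalence checks in under a minute.  These sizes
were chosen so that every stage (including the exact-DP oracle
comparisons) runs routinely on a laptop.  All stochastic steps — the
generator, the bootstrap, the null calibrations, the oracle sweeps — take
explicit integer seeds; profile-null calibration seeds derive from a CRC
of the profile name, so profiles are reproducible independently of build
order.

## Known limitations

- The maximum-likelihood tree inference used by large published surveys is
  deliberately replaced by NJ + bootstrap at this scale; externally
  computed trees can be imported as newick (`read_newick`) and used for
  classification unchanged.
- Type labels are ordinal by clade size, not matched to any published
  naming; comparisons against ground truth are therefore made up to a
  one-to-one relabelling.
- The profile scanner is ungapped within a placement; strongly
  indel-divergent domain instances would score lower than a full
  profile-HMM would.  Pre-computed domain hit tables can be supplied
  instead via the TSV import (`read_domain_hits_tsv`).
- The identity/similarity matrix can be asymmetric (alignments are
  query-dependent), and "N/D" conflates "no local alignment" with
  "alignment below thresholds" — both print identically, as in the
  published convention.
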
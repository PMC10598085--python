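import numpy as np
import pytest

from clp1kit.classify import CANONICAL_MOTIFS, scan_motifs
from clp1kit.simulate import (DEFAULT_LINEAGES, MOTIF_OFFSETS, SimulationConfig,
                              ablate_motif, generate_template_library,
                              load_template_library, simulate_dataset,
                              write_dataset)


def test_shipped_template_fasta_matches_generator():
    assert load_template_library() == generate_template_library()


def test_kinase_template_carries_canonical_motifs():
    p = load_template_library()["CLP1_P"]
    for name, off in MOTIF_OFFSETS.items():
        canon = CANONICAL_MOTIFS[name]
        assert p[off:off + len(canon)] == canon


class TestSimulateDataset:
    def test_every_record_has_exactly_one_truth_row(self, dataset):
        rec_ids = sorted(r.id for r in dataset.records)
        truth_ids = sorted(dataset.truth["id"])
        assert rec_ids == truth_ids

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_species=4)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        assert [(r.id, r.sequence) for r in d1.records] == \
               [(r.id, r.sequence) for r in d2.records]
        assert d1.truth.equals(d2.truth)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_dataset(d1, out1)
        write_dataset(d2, out2)
        for f in sorted(out1.iterdir()):
            assert f.read_bytes() == (out2 / f.name).read_bytes()

    def test_zero_substitution_rate_gives_identical_homologs(self):
        cfg = SimulationConfig(seed=2, n_species=4, substitution_rate=0.0,
                               isoform_prob=0.0, planted_duplicates=())
        ds = simulate_dataset(cfg)
        fam = ds.truth[~ds.truth.is_decoy]
        seqs = {r.id: r.sequence for r in ds.records}
        for lineage in fam.lineage.unique():
            members = fam[fam.lineage == lineage]["id"]
            assert len({seqs[m] for m in members}) == 1

    def test_planted_motifs_intact_at_zero_rate(self):
        cfg = SimulationConfig(seed=3, n_species=2, substitution_rate=0.0,
                               isoform_prob=0.0, planted_duplicates=())
        ds = simulate_dataset(cfg)
        truth = ds.truth.set_index("id")
        seqs = {r.id: r.sequence for r in ds.records}
        for rid, row in truth.iterrows():
            if row.is_decoy or row.is_isoform or row.lineage != "t2":
                continue
            # t2 plants all four motifs intact; locate the kinase span
            doms = dict(d.split(":") for d in row.domains.split(";"))
            s, e = map(int, doms["CLP1_P"].split("-"))
            span = seqs[rid][s - 1:e]
            report = scan_motifs(span)
            assert all(m.matched for m in report)

    def test_sister_species_divergence_matches_binomial_expectation(self):
        # two sister species are one substitution branch from their common
        # ancestor each: an unprotected site differs with probability
        # p = 2r(1-r) + r^2 * 18/19; motif sites are protected.
        import re
        rate = 0.04
        diffs = sites = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_species=4, isoform_prob=0.0,
                                   planted_duplicates=(), n_decoys=0)
            ds = simulate_dataset(cfg)
            seqs = {r.id: r.sequence for r in ds.records}
            pair = re.search(r"\((sp\d+):[\d.]+,(sp\d+):[\d.]+\)",
                             ds.species_tree_newick).groups()
            a, b = (seqs[f"{sp}_t2"] for sp in pair)
            n_protected = sum(len(m) for m in CANONICAL_MOTIFS.values())
            diffs += sum(x != y for x, y in zip(a, b))
            sites += len(a) - n_protected
        p = 2 * rate * (1 - rate) + rate ** 2 * 18 / 19
        sd = np.sqrt(p * (1 - p) / sites)
        assert abs(diffs / sites - p) <= 3 * sd

    def test_isoforms_are_truncations_with_parents(self, dataset):
        truth = dataset.truth
        seqs = {r.id: r.sequence for r in dataset.records}
        isos = truth[truth.is_isoform]
        assert len(isos) > 0
        for _, row in isos.iterrows():
            assert row.parent_id in seqs
            assert seqs[row.id] == seqs[row.parent_id][:len(seqs[row.id])]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(substitution_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_species=1)


class TestAblateMotif:
    def test_ablation_marks_lineage_inactive(self):
        cfg = ablate_motif(SimulationConfig(seed=4, n_species=2), "t2", "Lid")
        ds = simulate_dataset(cfg)
        t2 = ds.truth[(ds.truth.lineage == "t2") & ~ds.truth.is_isoform]
        assert (t2.activity == "inactive").all()
        assert all("Lid" not in m for m in t2.motifs_intact)

    def test_ablated_sites_break_the_pattern(self):
        cfg = ablate_motif(SimulationConfig(seed=4, n_species=2,
                                            substitution_rate=0.0,
                                            isoform_prob=0.0,
                                            planted_duplicates=()),
                           "t2", "Lid")
        ds = simulate_dataset(cfg)
        truth = ds.truth.set_index("id")
        seqs = {r.id: r.sequence for r in ds.records}
        rid = next(i for i in truth.index
                   if truth.loc[i, "lineage"] == "t2" and not truth.loc[i, "is_decoy"])
        doms = dict(d.split(":") for d in truth.loc[rid, "domains"].split(";"))
        s, e = map(int, doms["CLP1_P"].split("-"))
        report = {m.name: m.matched for m in scan_motifs(seqs[rid][s - 1:e])}
        assert not report["Lid"]
        assert report["WalkerA"] and report["WalkerB"] and report["Clasp"]

    def test_default_lineages_carry_expected_truth_activity(self, dataset):
        truth = dataset.truth[~dataset.truth.is_decoy]
        by_lineage = truth.groupby("lineage")["activity"].agg(set)
        assert by_lineage["t1"] == {"inactive"}   # Clasp-ablated
        assert by_lineage["t2"] == {"active"}
        assert by_lineage["nol9"] == {"inactive"}  # short kinase domain

    def test_unknown_names_rejected(self):
        with pytest.raises(KeyError):
            ablate_motif(SimulationConfig(), "t2", "NotAMotif")
        with pytest.raises(KeyError):
            ablate_motif(SimulationConfig(), "ghost", "Lid")
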
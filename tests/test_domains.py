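import numpy as np
import pytest

from clp1kit.domains import (DomainHit, Segment, assemble_architecture,
                             build_profile, discover_novel_domains,
                             read_domain_hits_tsv, scan_profiles,
                             unannotated_segments, write_domain_hits_tsv)
from clp1kit.msa import MultipleAlignment
from clp1kit.records import ProteinRecord
from clp1kit.simulate import load_template_library

from oracles import random_protein

RNG = np.random.default_rng(17)
TEMPLATES = load_template_library()


def seed_alignment(template, n=6, divergence=0.08, seed=0):
    from clp1kit.scoring import AA_ORDER
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        chars = list(template)
        for pos in rng.choice(len(chars), int(divergence * len(chars)), replace=False):
            chars[pos] = AA_ORDER[rng.integers(0, 20)]
        rows.append("".join(chars))
    return MultipleAlignment(tuple(f"s{i}" for i in range(n)), tuple(rows))


@pytest.fixture(scope="module")
def p_profile():
    return build_profile(seed_alignment(TEMPLATES["CLP1_P"]), "CLP1_P")


class TestBuildProfile:
    def test_identical_seed_gives_consensus_top_scores(self):
        s = random_protein(np.random.default_rng(1), 40)
        aln = MultipleAlignment(("a", "b", "c"), (s, s, s))
        prof = build_profile(aln, "X")
        from clp1kit.scoring import AA_INDEX
        top = prof.scores.argmax(axis=1)
        assert all(top[j] == AA_INDEX[s[j]] for j in range(40))

    def test_consensus_outscores_each_seed_row(self, p_profile):
        from clp1kit.scoring import AA_INDEX, AA_ORDER
        aln = seed_alignment(TEMPLATES["CLP1_P"])
        consensus = "".join(AA_ORDER[j] for j in p_profile.scores.argmax(axis=1))

        def full_score(seq):
            return sum(p_profile.scores[k, AA_INDEX[c]] for k, c in enumerate(seq))

        best_row = max(full_score(r) for r in aln.rows)
        assert full_score(consensus) >= best_row

    def test_random_background_scores_nonpositive_on_average(self, p_profile):
        rng = np.random.default_rng(3)
        from clp1kit.scoring import AA_INDEX
        totals = []
        for _ in range(200):
            seq = random_protein(rng, p_profile.length)
            totals.append(sum(p_profile.scores[k, AA_INDEX[c]]
                              for k, c in enumerate(seq)))
        assert np.mean(totals) <= 0

    def test_majority_gap_columns_excluded(self):
        aln = MultipleAlignment(("a", "b", "c"),
                                ("ACDEFGHIKLACDEFGHIKL" + "-" * 10,
                                 "ACDEFGHIKLACDEFGHIKL" + "-" * 10,
                                 "ACDEFGHIKLACDEFGHIKL" + "W" * 10))
        prof = build_profile(aln, "gappy")
        assert prof.length == 20

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            build_profile(MultipleAlignment(("a",), ("ACDEFGHIKL" * 3,)), "x")


class TestScanProfiles:
    def make_protein(self, rng, template="CLP1_P"):
        planted = TEMPLATES[template]
        seq = random_protein(rng, 120) + planted + random_protein(rng, 90)
        span = (121, 120 + len(planted))
        return ProteinRecord(id="prot", sequence=seq), span

    def test_planted_domain_found_covering_its_span(self, p_profile):
        protein, (s, e) = self.make_protein(np.random.default_rng(5))
        hits = scan_profiles(protein, [p_profile])
        assert len(hits) == 1
        h = hits[0]
        overlap = max(0, min(e, h.end) - max(s, h.start) + 1)
        assert overlap >= 0.9 * (e - s + 1)
        assert h.evalue <= 1e-3

    def test_shuffled_protein_yields_no_hit(self, p_profile):
        rng = np.random.default_rng(6)
        protein, _ = self.make_protein(rng)
        for _ in range(10):
            shuffled = "".join(rng.permutation(list(protein.sequence)))
            hits = scan_profiles(ProteinRecord(id="shuf", sequence=shuffled),
                                 [p_profile])
            assert hits == []

    def test_three_planted_domains_found_in_order(self):
        rng = np.random.default_rng(7)
        seq = (TEMPLATES["CLP1_EN"] + random_protein(rng, 8)
               + TEMPLATES["CLP1_P"] + random_protein(rng, 8)
               + TEMPLATES["CLP1_EC"])
        protein = ProteinRecord(id="full", sequence=seq)
        profiles = [build_profile(seed_alignment(TEMPLATES[n], seed=i), n)
                    for i, n in enumerate(("CLP1_EN", "CLP1_P", "CLP1_EC"))]
        hits = scan_profiles(protein, profiles)
        assert [h.domain_name for h in hits] == ["CLP1_EN", "CLP1_P", "CLP1_EC"]
        for h1, h2 in zip(hits, hits[1:]):
            assert h1.end < h2.start  # ordered and non-overlapping

    def test_profile_longer_than_protein_is_no_hit(self, p_profile):
        short = ProteinRecord(id="s", sequence=random_protein(RNG, 60))
        assert scan_profiles(short, [p_profile]) == []


class TestUnannotatedSegments:
    P400 = ProteinRecord(id="p", sequence="M" * 400)

    def test_no_hits_gives_whole_protein(self):
        assert unannotated_segments(self.P400, []) == [(1, 400)]

    def test_single_hit_complement(self):
        hits = [DomainHit("p", "D", 101, 200, 1.0, 0.0, "profile")]
        assert unannotated_segments(self.P400, hits) == [(1, 100), (201, 400)]

    def test_short_tail_suppressed(self):
        hits = [DomainHit("p", "D", 1, 370, 1.0, 0.0, "profile")]
        assert unannotated_segments(self.P400, hits, min_len=50) == []
        assert unannotated_segments(self.P400, hits, min_len=30) == [(371, 400)]


class TestNovelDomains:
    def build_segments(self, block, n, species_prefix="sp", start=201, seed=0):
        from clp1kit.scoring import AA_ORDER
        rng = np.random.default_rng(seed)
        segs = []
        for i in range(n):
            chars = list(block)
            for pos in rng.choice(len(chars), len(chars) // 10, replace=False):
                chars[pos] = AA_ORDER[rng.integers(0, 20)]
            seq = "".join(chars)
            segs.append(Segment(f"{species_prefix}{i}_prot", f"{species_prefix}{i}",
                                start, start + len(seq) - 1, seq))
        return segs

    def test_shared_block_becomes_one_domain(self):
        block = random_protein(np.random.default_rng(11), 150)
        segs = self.build_segments(block, 8)
        domains = discover_novel_domains(segs)
        assert len(domains) == 1
        nd = domains[0]
        assert len(nd.members) == 8
        assert nd.n_species == 8
        assert nd.mean_length == pytest.approx(150, abs=10)

    def test_disjoint_blocks_give_two_domains_without_cross_edges(self):
        rng = np.random.default_rng(12)
        segs = (self.build_segments(random_protein(rng, 140), 4, "alpha", seed=1)
                + self.build_segments(random_protein(rng, 120), 4, "beta", seed=2))
        domains = discover_novel_domains(segs)
        assert len(domains) == 2
        for nd in domains:
            prefixes = {h.protein_id.split("_")[0][:-1] for h in nd.members}
            assert len(prefixes) == 1  # no mixing between the two blocks

    def test_min_species_threshold(self):
        block = random_protein(np.random.default_rng(13), 100)
        segs = self.build_segments(block, 4)
        # force all members into 2 species only
        segs = [Segment(s.protein_id, f"sp{i % 2}", s.start, s.end, s.sequence)
                for i, s in enumerate(segs)]
        assert discover_novel_domains(segs, min_species=3) == []

    def test_member_order_invariance(self):
        block = random_protein(np.random.default_rng(14), 130)
        segs = self.build_segments(block, 5)
        d1 = discover_novel_domains(segs)
        d2 = discover_novel_domains(list(reversed(segs)))
        assert [sorted(h.protein_id for h in nd.members) for nd in d1] == \
               [sorted(h.protein_id for h in nd.members) for nd in d2]


class TestAssembleArchitecture:
    def test_profile_plus_novel_ordered_string(self):
        prot = ProteinRecord(id="p", sequence="M" * 500)
        prof = [DomainHit("p", "CLP1_eN", 1, 120, 50.0, 1e-10, "profile"),
                DomainHit("p", "CLP1_P", 130, 300, 80.0, 1e-20, "profile")]
        novel = [DomainHit("p", "NDOM1", 310, 460, 0.0, 0.0, "novel")]
        arch = assemble_architecture(prot, prof, novel)
        assert arch.string == "CLP1_eN|CLP1_P|NDOM1"
        assert arch.span_of("CLP1_P") == (130, 300)

    def test_two_domain_truncated_architecture(self):
        prot = ProteinRecord(id="p", sequence="M" * 300)
        prof = [DomainHit("p", "CLP1_eN", 1, 120, 50.0, 1e-10, "profile"),
                DomainHit("p", "CLP1_P", 130, 290, 80.0, 1e-20, "profile")]
        assert assemble_architecture(prot, prof).string == "CLP1_eN|CLP1_P"

    def test_empty_architecture(self):
        prot = ProteinRecord(id="p", sequence="M" * 100)
        arch = assemble_architecture(prot, [])
        assert arch.string == "" and arch.hits == ()

    def test_assembled_hits_never_overlap(self):
        prot = ProteinRecord(id="p", sequence="M" * 400)
        prof = [DomainHit("p", "A", 1, 200, 90.0, 1e-20, "profile"),
                DomainHit("p", "B", 180, 380, 70.0, 1e-15, "profile"),
                DomainHit("p", "C", 150, 260, 10.0, 1e-4, "profile")]
        arch = assemble_architecture(prot, prof)
        hits = arch.hits
        for h1, h2 in zip(hits, hits[1:]):
            assert h1.end < h2.start
        assert all(1 <= h.start <= h.end <= 400 for h in hits)


def test_domain_hits_tsv_round_trip(tmp_path):
    hits = [DomainHit("p1", "CLP1_P", 10, 180, 55.5, 1e-12, "profile"),
            DomainHit("p2", "NDOM1", 200, 340, 0.0, 0.0, "novel")]
    path = tmp_path / "hits.tsv"
    write_domain_hits_tsv(hits, path)
    back = read_domain_hits_tsv(path)
    assert [(h.protein_id, h.domain_name, h.start, h.end, h.origin)
            for h in back] == [(h.protein_id, h.domain_name, h.start, h.end,
                                h.origin) for h in hits]
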
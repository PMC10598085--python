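import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clp1kit.classify import (CANONICAL_MOTIFS, DEFAULT_MOTIFS, GROUP_CLP1,
                              GROUP_NOL9, GroupSplitError, MotifMatch,
                              assign_types, identity_matrix, predict_activity,
                              scan_motifs, split_groups)
from clp1kit.records import ProteinRecord
from clp1kit.tree import read_newick

from oracles import random_protein

RNG = np.random.default_rng(31)


def kinase_span(rng, length=170, ablate=()):
    """Synthetic kinase-domain span with canonical motifs planted in order."""
    offsets = {"WalkerA": 12, "WalkerB": 58, "Clasp": 108, "Lid": 148}
    chars = list(random_protein(rng, length))
    for name, off in offsets.items():
        if off + len(CANONICAL_MOTIFS[name]) > length:
            continue
        motif = CANONICAL_MOTIFS[name]
        if name in ablate:
            motif = motif[::-1]  # scrambled residues break the pattern
        chars[off:off + len(motif)] = motif
    return "".join(chars)


class TestScanMotifs:
    def test_all_four_found_in_order(self):
        span = kinase_span(np.random.default_rng(1))
        report = scan_motifs(span)
        assert all(m.matched for m in report)
        positions = [m.position for m in report]
        assert positions == sorted(positions)

    def test_scrambled_clasp_unmatched(self):
        span = kinase_span(np.random.default_rng(2), ablate=("Clasp",))
        report = {m.name: m.matched for m in scan_motifs(span)}
        assert report == {"WalkerA": True, "WalkerB": True,
                          "Clasp": False, "Lid": True}

    def test_truncated_span_loses_late_motifs(self):
        span = kinase_span(np.random.default_rng(3))[:55]
        report = {m.name: m.matched for m in scan_motifs(span)}
        assert not report["Clasp"] and not report["Lid"]

    def test_empty_span_matches_nothing(self):
        assert all(not m.matched for m in scan_motifs(""))


class TestPredictActivity:
    def report(self, matched=4):
        names = [m.name for m in DEFAULT_MOTIFS]
        return tuple(MotifMatch(n, i < matched, i + 1 if i < matched else None,
                                None) for i, n in enumerate(names))

    def test_full_motifs_and_length_active(self):
        assert predict_activity(self.report(4), 170) == "active"

    def test_any_unmatched_motif_inactive(self):
        assert predict_activity(self.report(3), 170) == "inactive"

    def test_short_domain_inactive_regardless(self):
        assert predict_activity(self.report(4), 55) == "inactive"
        assert predict_activity(self.report(4), 129) == "inactive"
        assert predict_activity(self.report(4), 130) == "active"

    def test_missing_domain_unknown(self):
        assert predict_activity(self.report(4), None) == "unknown"

    @given(st.integers(0, 4), st.integers(0, 4), st.integers(40, 300))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_motif_matches(self, m1, m2, length):
        lo, hi = sorted((m1, m2))
        a_lo = predict_activity(self.report(lo), length)
        a_hi = predict_activity(self.report(hi), length)
        # adding a motif match never flips active -> inactive
        if a_lo == "active":
            assert a_hi == "active"


class TestSplitGroups:
    def test_two_clade_tree_labelled_by_anchors(self):
        t = read_newick("((a1:1,a2:1):2,(b1:1,b2:1):2);")
        groups = split_groups(t, {"a1": GROUP_CLP1, "b1": GROUP_NOL9})
        assert groups == {"a1": GROUP_CLP1, "a2": GROUP_CLP1,
                          "b1": GROUP_NOL9, "b2": GROUP_NOL9}

    def test_conflicting_anchors_raise(self):
        t = read_newick("((a1:1,a2:1):2,(b1:1,b2:1):2);")
        with pytest.raises(GroupSplitError):
            split_groups(t, {"a1": GROUP_CLP1, "a2": GROUP_NOL9,
                             "b1": GROUP_NOL9, "b2": GROUP_CLP1})

    def test_anchor_free_subtree_is_unknown(self):
        t = read_newick("((a1:1,a2:1):2,(b1:1,b2:1):2);")
        groups = split_groups(t, {"a1": GROUP_CLP1})
        assert groups["b1"] == "unknown" and groups["b2"] == "unknown"


class TestAssignTypes:
    def build(self, n_species=4):
        # three lineages, one clade each; lineage x has a distinct architecture
        newick = "(" + ",".join(
            "(" + ",".join(f"sp{s}_{lin}:1" for s in range(n_species)) + "):2"
            for lin in ("x", "y", "z")) + ");"
        tree = read_newick(newick)
        members = [f"sp{s}_{lin}" for lin in ("x", "y", "z")
                   for s in range(n_species)]
        species = {m: m.split("_")[0] for m in members}
        archs = {m: f"EN|P|C{m.split('_')[1]}" for m in members}
        return tree, members, species, archs

    def test_three_lineages_get_three_types(self):
        tree, members, species, archs = self.build()
        ta = assign_types(members, species, tree, archs)
        assert sorted(set(ta.labels.values())) == ["t1", "t2", "t3"]
        for m in members:
            same = [o for o in members if o.split("_")[1] == m.split("_")[1]]
            assert len({ta.labels[o] for o in same}) == 1

    def test_single_duplicate_tolerated_and_flagged(self):
        tree, members, species, archs = self.build()
        # graft a duplicate of sp0_x into the x clade
        from skbio import TreeNode
        x_clade = None
        for node in tree.non_tips():
            if {t.name for t in node.tips()} == {f"sp{s}_x" for s in range(4)}:
                x_clade = node
        dup = TreeNode(name="sp0_xdup", length=0.1)
        x_clade.append(dup)
        members = members + ["sp0_xdup"]
        species["sp0_xdup"] = "sp0"
        archs["sp0_xdup"] = archs["sp0_x"]
        ta = assign_types(members, species, tree, archs)
        assert ta.labels["sp0_xdup"] == ta.labels["sp0_x"]
        assert {"sp0_x", "sp0_xdup"} <= set(ta.flagged_duplicates)

    def test_same_species_members_get_letter_suffixes(self):
        # three co-occurring members of one species: no cross-species clade
        tree = read_newick("((m1:1,m2:1):1,(m3:1,outg:5):1);")
        members = ["m1", "m2", "m3"]
        species = {"m1": "spA", "m2": "spA", "m3": "spA", "outg": "spB"}
        archs = {m: "EN|P" for m in members} | {"outg": "EN|P"}
        ta = assign_types(members, species, tree, archs)
        assert sorted(ta.labels[m] for m in members) == ["a", "b", "c"]

    def test_singleton_gets_no_decoration(self):
        tree = read_newick("((m1:1,outg:1):1,far:3);")
        ta = assign_types(["m1"], {"m1": "spA"}, tree, {"m1": "EN|P"})
        assert ta.labels["m1"] == ""

    def test_member_missing_from_tree_raises(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(KeyError):
            assign_types(["ghost"], {"ghost": "sp"}, tree, {})


class TestIdentityMatrix:
    def make_members(self):
        rng = np.random.default_rng(41)
        base = random_protein(rng, 200)
        related = list(base)
        for pos in rng.choice(200, 60, replace=False):
            related[pos] = random_protein(rng, 1)
        unrelated = random_protein(rng, 220)
        return [ProteinRecord(id="m1", sequence=base, species="sp"),
                ProteinRecord(id="m2", sequence="".join(related), species="sp"),
                ProteinRecord(id="m3", sequence=unrelated, species="sp")]

    def test_diagonal_dash_and_nd_for_undetected(self):
        m = identity_matrix(self.make_members())
        assert all(m.loc[i, i] == "–" for i in m.index)
        assert m.loc["m1", "m3"] == "N/D"
        assert m.loc["m3", "m1"] == "N/D"

    def test_cells_are_identity_similarity_pairs(self):
        m = identity_matrix(self.make_members())
        cell = m.loc["m1", "m2"]
        ident, sim = cell.replace("(", "").replace(")", "").split()
        assert 0 <= int(ident) <= int(sim) <= 100

    def test_identical_pair_reads_100_100(self):
        s = random_protein(np.random.default_rng(43), 150)
        m = identity_matrix([ProteinRecord(id="a", sequence=s),
                             ProteinRecord(id="b", sequence=s)])
        assert m.loc["a", "b"] == "100 (100)"

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            identity_matrix([ProteinRecord(id="only", sequence="MKLV" * 30)])
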
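import math

import numpy as np
import pytest

from clp1kit.records import ProteinRecord
from clp1kit.scoring import ScoringScheme
from clp1kit.search import (SearchParams, build_inventory, dual_query_search,
                            evalue, bit_score, search_local, write_hits_tsv)

from oracles import random_protein, smith_waterman_score

SCHEME = ScoringScheme()
RNG = np.random.default_rng(42)


def rec(i, seq, species="spX", **kw):
    return ProteinRecord(id=i, sequence=seq, species=species, **kw)


class TestEvalue:
    def test_direct_formula(self):
        # K*m*n*exp(-lambda*S) with the gapped BLOSUM62/11/1 constants
        e = evalue(40, 100, 100, SCHEME)
        assert e == pytest.approx(0.041 * 1e4 * math.exp(-0.267 * 40), rel=1e-12)
        assert e == pytest.approx(9.4e-3, rel=0.02)

    def test_monotone_in_score_and_linear_in_n(self):
        assert evalue(50, 100, 100, SCHEME) < evalue(40, 100, 100, SCHEME)
        assert evalue(40, 100, 200, SCHEME) == pytest.approx(
            2 * evalue(40, 100, 100, SCHEME))

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            evalue(40, 0, 100, SCHEME)

    def test_bit_score_definition(self):
        assert bit_score(40, SCHEME) == pytest.approx(
            (0.267 * 40 - math.log(0.041)) / math.log(2))


class TestSearchLocal:
    def test_self_match(self):
        q = rec("q", random_protein(RNG, 200))
        hits = search_local(q, [rec("t", q.sequence)])
        assert len(hits) == 1
        h = hits[0]
        assert h.identity_pct == 100
        assert h.coverage == pytest.approx(1.0)
        assert h.evalue < 1e-4

    def test_query_coverage_boundary(self):
        query = rec("q", random_protein(RNG, 200))
        at_boundary = rec("t60", query.sequence[50:110])   # 60/200 = 0.30
        below = rec("t58", query.sequence[50:108])         # 58/200 = 0.29
        hits = search_local(query, [at_boundary, below])
        assert [h.target_id for h in hits] == ["t60"]
        assert hits[0].coverage == pytest.approx(0.30)

    def test_every_hit_obeys_thresholds_and_bounds(self):
        params = SearchParams()
        q = rec("q", random_protein(RNG, 150))
        db = [rec(f"t{i}", random_protein(RNG, 180)) for i in range(5)]
        db.append(rec("rel", q.sequence[:100] + random_protein(RNG, 60)))
        for h in search_local(q, db, params):
            assert h.evalue <= params.evalue_max
            assert h.coverage >= params.coverage_min
            assert 1 <= h.q_start <= h.q_end <= len(q.sequence)
            target = next(t for t in db if t.id == h.target_id)
            assert 1 <= h.t_start <= h.t_end <= len(target.sequence)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            search_local(rec("q", "MK"), [rec("t", random_protein(RNG, 30))])

    @pytest.mark.parametrize("pair_seed", range(12))
    def test_best_score_matches_exhaustive_smith_waterman(self, pair_seed):
        rng = np.random.default_rng(1000 + pair_seed)
        a = random_protein(rng, int(rng.integers(40, 300)))
        # half related pairs, half unrelated
        if pair_seed % 2:
            b = list(a)
            for pos in rng.choice(len(b), size=len(b) // 4, replace=False):
                b[pos] = random_protein(rng, 1)
            b = "".join(b)
        else:
            b = random_protein(rng, int(rng.integers(40, 300)))
        from clp1kit.search import best_local_alignment
        aln = best_local_alignment(a, b, SearchParams())
        expected = smith_waterman_score(a, b)
        got = aln.score if aln is not None else 0
        assert got == expected


class TestDualQuery:
    def make_db(self):
        fam = random_protein(RNG, 300)
        members = [rec(f"m{i}", fam[:150] + random_protein(RNG, 20) + fam[150:])
                   for i in range(3)]
        others = [rec(f"o{i}", random_protein(RNG, 250)) for i in range(2)]
        return fam, members + others

    def test_union_without_duplicates(self):
        fam, db = self.make_db()
        full = [rec("qf", fam)]
        dom = [rec("qd", fam[50:220])]
        merged = dual_query_search(full, dom, db)
        ids = [h.target_id for h in merged]
        assert ids == sorted(set(ids))  # each target once
        both = [h for h in merged if h.query_class == "domain+full"]
        assert both  # members found by both query classes collapse to one row

    def test_invariant_to_query_order(self):
        fam, db = self.make_db()
        q1 = [rec("qa", fam), rec("qb", fam[30:280])]
        r1 = dual_query_search(q1, [], db)
        r2 = dual_query_search(list(reversed(q1)), [], db)
        assert [(h.target_id, h.evalue) for h in r1] == \
               [(h.target_id, h.evalue) for h in r2]

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            dual_query_search([rec("q", random_protein(RNG, 50))], [], [])


class TestInventory:
    def test_counts_isoforms_and_zero_species(self):
        gene = random_protein(RNG, 120)
        records = [
            rec("a_g1", gene, species="A"),
            rec("a_g1.iso1", gene[:80], species="A", is_isoform=True),
            rec("a_g1.iso2", gene[:60], species="A", is_isoform=True),
            rec("a_g2", random_protein(RNG, 100), species="A"),
            rec("b_only", random_protein(RNG, 90), species="B"),
        ]
        hits = search_local(rec("q", gene), records)
        rows, summary = build_inventory(hits, records)
        by_sp = {r.species: r for r in rows}
        assert by_sp["A"].n_family_records == 3
        assert by_sp["A"].n_genes == 1
        assert by_sp["A"].representative_ids == ("a_g1",)  # longest wins
        assert by_sp["B"].n_family_records == 0  # zero-hit species listed
        assert summary.defined and summary.n_species_with_members == 1

    def test_empty_hits_summary_undefined(self):
        records = [rec("x", random_protein(RNG, 50), species="A")]
        rows, summary = build_inventory([], records)
        assert rows[0].n_genes == 0
        assert not summary.defined

    def test_unknown_target_raises(self):
        q = rec("q", random_protein(RNG, 80))
        db = [rec("t", q.sequence)]
        hits = search_local(q, db)
        with pytest.raises(KeyError):
            build_inventory(hits, [rec("other", "MKLV", species="A")])


def test_hits_tsv_has_twelve_columns(tmp_path):
    q = rec("q", random_protein(RNG, 100))
    hits = search_local(q, [rec("t", q.sequence)])
    out = tmp_path / "hits.tsv"
    write_hits_tsv(hits, out)
    fields = out.read_text().strip().split("\t")
    assert len(fields) == 12
    assert fields[0] == "q" and fields[1] == "t"
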
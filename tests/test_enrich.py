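import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ndseq.enrich import (
    GeneSetCollection,
    RankedList,
    gsea_es,
    gsea_preranked,
    hypergeom_enrich,
    rank_genes,
    read_gmt,
    write_gmt,
)


def brute_force_es(ranked: RankedList, members, weight=1.0):
    """Running sum evaluated explicitly at every prefix."""
    members = set(members)
    hits = [g in members for g in ranked.genes]
    m = sum(hits)
    n = len(ranked)
    tot = sum(abs(s) ** weight for s, h in zip(ranked.scores, hits) if h)
    run, hi, lo = 0.0, 0.0, 0.0
    for s, h in zip(ranked.scores, hits):
        if h:
            run += (abs(s) ** weight / tot) if tot > 0 else 1.0 / m
        else:
            run -= 1.0 / (n - m)
        hi, lo = max(hi, run), min(lo, run)
    # same positive-preferring tie rule as the implementation
    return hi if hi >= -lo - 1e-9 else lo


@pytest.fixture
def four_gene_list():
    return RankedList(
        np.array(["g1", "g2", "g3", "g4"], dtype=object),
        np.array([4.0, 3.0, 2.0, 1.0]),
    )


class TestRankGenes:
    def frame(self, genes, lors):
        return pd.DataFrame(
            {"lor": lors, "contrast": "X"}, index=pd.Index(genes, name="gene_id")
        )

    def test_descending_order(self):
        ranked = rank_genes(self.frame(["a", "b", "c"], [2.0, -1.0, 0.5]))
        assert list(ranked.genes) == ["a", "c", "b"]

    def test_tie_break_by_gene_id(self):
        ranked = rank_genes(self.frame(["b", "a"], [1.0, 1.0]))
        assert list(ranked.genes) == ["a", "b"]

    def test_sign_reversal_reverses_order(self):
        rng = np.random.default_rng(0)
        lors = rng.normal(size=20)  # continuous: ties have measure zero
        genes = [f"g{i}" for i in range(20)]
        fwd = rank_genes(self.frame(genes, lors))
        rev = rank_genes(self.frame(genes, -lors))
        assert list(rev.genes) == list(fwd.genes)[::-1]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rank_genes(self.frame(["a", "a"], [1.0, 2.0]))


class TestGseaES:
    def test_top_gene_set_scores_one(self, four_gene_list):
        assert gsea_es(four_gene_list, {"g1"}) == pytest.approx(1.0)

    def test_bottom_gene_set_scores_minus_one(self, four_gene_list):
        assert gsea_es(four_gene_list, {"g4"}) == pytest.approx(-1.0)

    def test_symmetric_scores_middle_set_matches_brute_force(self):
        ranked = RankedList(
            np.array(["g1", "g2", "g3", "g4"], dtype=object),
            np.array([2.0, 1.0, -1.0, -2.0]),
        )
        es = gsea_es(ranked, {"g2", "g3"})
        assert es == pytest.approx(brute_force_es(ranked, {"g2", "g3"}), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_universes(self, data):
        n = data.draw(st.integers(6, 50))
        seed = data.draw(st.integers(0, 10**6))
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        m = data.draw(st.integers(1, n - 1))
        members = set(rng.choice(genes, size=m, replace=False))
        weight = data.draw(st.sampled_from([0.0, 1.0]))
        ranked = RankedList(genes, scores)
        assert gsea_es(ranked, members, weight) == pytest.approx(
            brute_force_es(ranked, members, weight), abs=1e-12
        )

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(1)
        half = np.sort(rng.uniform(0.1, 3, size=10))[::-1]
        scores = np.concatenate([half, -half[::-1]])  # symmetric about zero
        genes = np.array([f"g{i:02d}" for i in range(20)], dtype=object)
        members = set(rng.choice(genes, size=6, replace=False))
        fwd = RankedList(genes, scores)
        rev = RankedList(genes[::-1].copy(), scores[::-1].copy())
        assert gsea_es(rev, members) == pytest.approx(-gsea_es(fwd, members), abs=1e-12)

    def test_disjoint_or_covering_set_rejected(self, four_gene_list):
        with pytest.raises(ValueError):
            gsea_es(four_gene_list, {"absent"})
        with pytest.raises(ValueError):
            gsea_es(four_gene_list, {"g1", "g2", "g3", "g4"})


@pytest.fixture(scope="module")
def null_ranked():
    rng = np.random.default_rng(2)
    genes = np.array([f"g{i:03d}" for i in range(300)], dtype=object)
    scores = np.sort(rng.normal(size=300))[::-1]
    return RankedList(genes, scores)


class TestGseaPreranked:
    def test_same_seed_reproduces(self, null_ranked):
        coll = GeneSetCollection(
            {f"s{i}": [f"g{j:03d}" for j in range(i * 10, i * 10 + 15)] for i in range(5)}
        )
        a = gsea_preranked(null_ranked, coll, n_perm=200, seed=9)
        b = gsea_preranked(null_ranked, coll, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_null_pvalues_roughly_uniform(self, null_ranked):
        rng = np.random.default_rng(3)
        coll = GeneSetCollection(
            {
                f"s{i}": list(rng.choice(null_ranked.genes, 20, replace=False))
                for i in range(40)
            }
        )
        res = gsea_preranked(null_ranked, coll, n_perm=500, seed=4)
        assert 0.2 < res["p"].mean() < 0.8
        assert (res["p"] > 0).all() and (res["p"] <= 1).all()

    def test_small_sets_skipped(self, null_ranked):
        coll = GeneSetCollection({"tiny": ["g000", "g001"], "ok": [f"g{j:03d}" for j in range(10)]})
        res = gsea_preranked(null_ranked, coll, n_perm=100, seed=0)
        assert list(res.index) == ["ok"]

    def test_q_monotone_in_p(self, null_ranked):
        rng = np.random.default_rng(5)
        coll = GeneSetCollection(
            {
                f"s{i}": list(rng.choice(null_ranked.genes, 15, replace=False))
                for i in range(20)
            }
        )
        res = gsea_preranked(null_ranked, coll, n_perm=200, seed=1).sort_values("p")
        assert (res["q"].diff().dropna() >= -1e-12).all()

    def test_empty_collection_rejected(self, null_ranked):
        with pytest.raises(ValueError):
            gsea_preranked(null_ranked, GeneSetCollection({}), n_perm=100, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            gsea_preranked(
                null_ranked, GeneSetCollection({"s": ["g000"] * 1 + ["g001"]}), n_perm=10
            )


class TestHypergeom:
    def test_full_overlap_exact_value(self):
        universe = [f"g{i}" for i in range(10)]
        coll = GeneSetCollection({"s": universe[:5]})
        res = hypergeom_enrich(universe[:5], universe, coll)
        assert res.loc["s", "p"] == pytest.approx(1 / 252, abs=1e-12)

    def test_partial_overlap_exact_value(self):
        universe = ["a", "b", "c", "d"]
        coll = GeneSetCollection({"s": ["a", "b"]})
        res = hypergeom_enrich(["a", "c"], universe, coll)
        assert res.loc["s", "p"] == pytest.approx(5 / 6, abs=1e-12)

    def test_set_equal_to_universe_certain(self):
        universe = ["a", "b", "c"]
        coll = GeneSetCollection({"s": universe})
        res = hypergeom_enrich(["a"], universe, coll)
        assert res.loc["s", "p"] == pytest.approx(1.0)
        assert res.loc["s", "overlap"] == 1

    def test_query_outside_universe_rejected(self):
        coll = GeneSetCollection({"s": ["a"]})
        with pytest.raises(ValueError, match="outside"):
            hypergeom_enrich(["z"], ["a", "b"], coll)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"alpha": ["g1", "g2"], "beta": ["g3"]},
            descriptions={"alpha": "first", "beta": "second"},
        )
        path = tmp_path / "c.gmt"
        write_gmt(coll, str(path))
        assert read_gmt(str(path)) == coll

    def test_two_field_line_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ok\tdesc\tg1\nbroken\tdesc\n")
        with pytest.raises(ValueError, match="2"):
            read_gmt(str(path))

    def test_trailing_tabs_ignored(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("s\tdesc\tg1\tg2\t\t\n")
        assert read_gmt(str(path))["s"] == ["g1", "g2"]

    def test_duplicate_set_names_rejected(self, tmp_path):
        path = tmp_path / "d.gmt"
        path.write_text("s\tdesc\tg1\ns\tdesc\tg2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(str(path))

    def test_duplicate_members_deduplicated_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            coll = GeneSetCollection({"s": ["g1", "g1", "g2"]})
        assert coll["s"] == ["g1", "g2"]
        assert "duplicate" in caplog.text

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetCollection({"s": []})
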
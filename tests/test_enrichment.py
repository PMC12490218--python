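import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisprog.enrichment import (
    GeneSetCollection,
    GmtFormatError,
    GseaResult,
    enrichment_score,
    filter_results,
    gsea_preranked,
    read_gmt,
)


def brute_force_es(genes, weights, gene_set):
    """Literal running-sum oracle: walk the ranking, track the full statistic."""
    hits = [g in set(gene_set) for g in genes]
    total_hit_weight = sum(abs(w) for w, h in zip(weights, hits) if h)
    n_miss = len(genes) - sum(hits)
    running = []
    cur = 0.0
    for w, h in zip(weights, hits):
        if h:
            if total_hit_weight > 0:
                cur += abs(w) / total_hit_weight
            else:
                cur += 1.0 / sum(hits)
        else:
            cur -= 1.0 / n_miss
        running.append(cur)
    mx, mn = max(running), min(running)
    return mx if mx >= -mn else mn


def _ranking(weights):
    return pd.Series(
        sorted(weights, reverse=True), index=[f"g{i}" for i in range(len(weights))]
    )


class TestReadGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("SET1\tdesc\tA\tB\tC\n")
        coll = read_gmt(p)
        assert coll.sets == {"SET1": ["A", "B", "C"]}

    def test_empty_file(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0

    def test_duplicate_gene_deduplicated_with_warning(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("S\td\tA\tB\tA\n")
        with pytest.warns(RuntimeWarning, match="duplicated"):
            coll = read_gmt(p)
        assert coll.sets["S"] == ["A", "B"]

    def test_short_line_raises_with_line_number(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("GOOD\td\tA\nBAD\tonly-desc\n")
        with pytest.raises(GmtFormatError, match=":2"):
            read_gmt(p)


class TestEnrichmentScore:
    def test_whole_ranking_set_scores_one(self):
        ranking = _ranking([3.0, 2.0, 1.0, 0.5])
        es, running, leading = enrichment_score(ranking, list(ranking.index))
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(1.0)

    def test_top_gene_set(self):
        ranking = _ranking([3.0, 2.0, 1.0, 0.5])
        es, _, leading = enrichment_score(ranking, ["g0"])
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_bottom_gene_set_is_negative(self):
        ranking = _ranking([3.0, 2.0, 1.0, 0.5])
        es, _, leading = enrichment_score(ranking, ["g3"])
        assert es == pytest.approx(-1.0)
        assert leading == ["g3"]

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="intersect"):
            enrichment_score(_ranking([2.0, 1.0]), ["absent"])

    def test_reversal_negates_score_on_symmetric_toy(self):
        weights = [4.0, 3.0, -3.0, -4.0]
        ranking = _ranking(weights)
        rev = pd.Series(
            sorted([-w for w in weights], reverse=True),
            index=list(ranking.index[::-1]),
        )
        for subset in (["g0"], ["g0", "g1"], ["g1"]):
            es_fwd, _, _ = enrichment_score(ranking, subset)
            es_rev, _, _ = enrichment_score(rev, subset)
            assert es_rev == pytest.approx(-es_fwd)

    def test_matches_brute_force_all_subsets_eight_genes(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            weights = np.round(np.sort(rng.normal(size=8))[::-1], 3)
            ranking = pd.Series(weights, index=[f"g{i}" for i in range(8)])
            genes = list(ranking.index)
            for r in range(1, 9):
                for subset in itertools.combinations(genes, r):
                    es, _, _ = enrichment_score(ranking, list(subset))
                    oracle = brute_force_es(genes, weights, subset)
                    assert es == pytest.approx(oracle, abs=1e-12)

    @given(
        weights=st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=3, max_size=8
        ),
        mask=st.lists(st.booleans(), min_size=3, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_in_unit_interval_and_matches_oracle(self, weights, mask):
        n = min(len(weights), len(mask))
        weights, mask = weights[:n], mask[:n]
        if not any(mask):
            return
        ranking = _ranking(weights)
        subset = [g for g, m in zip(ranking.index, mask) if m]
        es, _, _ = enrichment_score(ranking, subset)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert es == pytest.approx(
            brute_force_es(list(ranking.index), ranking.to_numpy(), subset), abs=1e-12
        )


class TestGseaPreranked:
    def _planted(self, seed=0, n=2000, k=50):
        rng = np.random.default_rng(seed)
        weights = np.sort(rng.normal(size=n))[::-1]
        ranking = pd.Series(weights, index=[f"g{i:04d}" for i in range(n)])
        top_set = list(ranking.index[:k])
        decoys = {
            f"RANDOM{j}": list(rng.choice(ranking.index, 40, replace=False))
            for j in range(5)
        }
        coll = GeneSetCollection(sets={"PLANTED_TOP": top_set, **decoys})
        return ranking, coll

    def test_planted_top_set_detected(self):
        ranking, coll = self._planted()
        results = {r.set_name: r for r in gsea_preranked(ranking, coll, seed=1)}
        top = results["PLANTED_TOP"]
        assert top.nes > 0
        assert top.fdr < 0.05
        assert top.gene_ratio > 0.4

    def test_size_filter_excludes_small_sets(self):
        ranking, _ = self._planted()
        coll = GeneSetCollection(sets={"TINY": list(ranking.index[:10])})
        with pytest.warns(RuntimeWarning, match="size filter"):
            assert gsea_preranked(ranking, coll, min_size=15, seed=0) == []

    def test_seeded_determinism(self):
        ranking, coll = self._planted()
        a = gsea_preranked(ranking, coll, n_perm=200, seed=3)
        b = gsea_preranked(ranking, coll, n_perm=200, seed=3)
        assert [(r.set_name, r.p_value, r.nes) for r in a] == [
            (r.set_name, r.p_value, r.nes) for r in b
        ]

    def test_duplicate_genes_rejected(self):
        ranking = pd.Series([2.0, 1.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            gsea_preranked(ranking, GeneSetCollection(sets={"S": ["a"]}))

    def test_null_pvalues_roughly_uniform(self):
        """Random sets on a random ranking give a flat p-value distribution."""
        from scipy.stats import kstest

        rng = np.random.default_rng(10)
        n = 500
        ranking = pd.Series(
            np.sort(rng.normal(size=n))[::-1], index=[f"g{i}" for i in range(n)]
        )
        sets = {
            f"S{j}": list(rng.choice(ranking.index, 20, replace=False))
            for j in range(200)
        }
        results = gsea_preranked(
            ranking, GeneSetCollection(sets=sets), n_perm=500, seed=11
        )
        pvals = np.array([r.p_value for r in results])
        assert kstest(pvals, "uniform").statistic < 0.12

    def test_bh_fdr_monotone_in_p_order(self):
        ranking, coll = self._planted(seed=5)
        results = gsea_preranked(ranking, coll, n_perm=300, seed=5)
        ordered = sorted(results, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_agrees_with_independent_gsea_implementation(self):
        """Observed enrichment scores match gseapy on the same input."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(21)
        n = 300
        ranking = pd.Series(
            np.sort(rng.normal(size=n))[::-1], index=[f"g{i}" for i in range(n)]
        )
        sets = {
            "A": list(rng.choice(ranking.index, 30, replace=False)),
            "B": list(ranking.index[:20]),
        }
        ours = {
            r.set_name: r.es
            for r in gsea_preranked(ranking, GeneSetCollection(sets=sets), n_perm=10, seed=0)
        }
        ref = gseapy.prerank(
            rnk=ranking.reset_index(), gene_sets=sets, permutation_num=10,
            min_size=5, max_size=500, seed=1, outdir=None, no_plot=True, threads=1,
        ).res2d.set_index("Term")["ES"]
        for name in sets:
            assert ours[name] == pytest.approx(float(ref[name]), abs=1e-9)


class TestFilterResults:
    def _res(self, fdr, ratio):
        return GseaResult("s", 0.5, 1.0, 0.01, fdr, 20, ["a"], ratio)

    def test_filtering(self):
        kept = filter_results([self._res(0.01, 0.5), self._res(0.01, 0.3), self._res(0.2, 0.9)])
        assert len(kept) == 1
        assert filter_results([]) == []
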
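"""Gene ranking, pre-ranked GSEA, ssGSEA, and correlation analyses."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spliceburden.diffsplice import DifferentialEvent
from spliceburden.enrichment import (
    correlate_with_adjustment,
    correlated_target_proportion,
    gsea_preranked,
    gsea_preranked_collection,
    rank_genes,
    ssgsea_score,
)
from spliceburden.types import GeneSet


def _dev(eid, q):
    return DifferentialEvent(eid, "SE", 0.2, q / 2, q, "none", False)


class TestRankGenes:
    def test_splicing_score_uses_min_q_per_gene(self):
        events = [_dev("e1", 0.01), _dev("e2", 0.2)]
        ranking = rank_genes("splicing", diff_events=events,
                             event_genes={"e1": "GA", "e2": "GA"})
        assert ranking["GA"] == pytest.approx(2.0)

    def test_expression_score_signed(self):
        de = pd.DataFrame({"gene": ["up", "down", "flat"],
                           "log2fc": [1.5, -2.0, 0.5],
                           "padj": [0.01, 0.001, 1.0]})
        ranking = rank_genes("expression", de_table=de)
        assert ranking["down"] == pytest.approx(-3.0)
        assert ranking["flat"] == pytest.approx(0.0)
        assert list(ranking.index)[0] == "up"  # sorted descending

    def test_zero_p_clamped_finite(self):
        de = pd.DataFrame({"gene": ["g"], "log2fc": [1.0], "padj": [0.0]})
        assert np.isfinite(rank_genes("expression", de_table=de)["g"])


def _hand_es(scores, hits, weight=1.0):
    """Independent running-sum oracle: explicit loop, no vectorization."""
    n, cur, best = len(scores), 0.0, 0.0
    total_hit = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    n_miss = n - sum(hits)
    for s, h in zip(scores, hits):
        cur += (abs(s) ** weight / total_hit) if h else (-1.0 / n_miss)
        if abs(cur) > abs(best):
            best = cur
    return best


class TestGseaPreranked:
    def test_top_gene_singleton_set_gives_unit_es(self):
        ranking = pd.Series([3.0, 2.0, 1.0, 0.0], index=list("abcd"))
        res = gsea_preranked(ranking, GeneSet.of("s", ["a"]), n_perm=50, seed=1)
        assert res.es == pytest.approx(1.0)

    @pytest.mark.parametrize("hits", [(0, 3), (1, 4), (2,), (0, 1, 5)])
    def test_matches_hand_running_sum_on_small_rankings(self, hits):
        scores = [5.0, 4.0, 3.0, 2.0, 1.0, 0.5]
        genes = [f"g{i}" for i in range(6)]
        ranking = pd.Series(scores, index=genes)
        gs = GeneSet.of("s", [genes[i] for i in hits])
        res = gsea_preranked(ranking, gs, n_perm=20, seed=3)
        mask = [i in hits for i in range(6)]
        assert res.es == pytest.approx(_hand_es(scores, mask), abs=1e-12)
        assert abs(res.es) <= 1.0 + 1e-12

    def test_full_coverage_and_empty_intersection_rejected(self):
        ranking = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError, match="entire ranking"):
            gsea_preranked(ranking, GeneSet.of("all", ["a", "b"]), n_perm=10)
        with pytest.raises(ValueError, match="no genes"):
            gsea_preranked(ranking, GeneSet.of("none", ["zz"]), n_perm=10)

    def test_same_seed_bit_reproducible(self):
        rng = np.random.default_rng(12)
        ranking = pd.Series(np.sort(rng.normal(size=40))[::-1],
                            index=[f"g{i}" for i in range(40)])
        gs = GeneSet.of("s", [f"g{i}" for i in (1, 5, 9, 20)])
        r1 = gsea_preranked(ranking, gs, n_perm=200, seed=7)
        r2 = gsea_preranked(ranking, gs, n_perm=200, seed=7)
        assert (r1.es, r1.nes, r1.p_value) == (r2.es, r2.nes, r2.p_value)

    def test_random_sets_have_abs_nes_near_one(self):
        rng = np.random.default_rng(13)
        ranking = pd.Series(np.sort(rng.normal(size=100))[::-1],
                            index=[f"g{i}" for i in range(100)])
        nes = []
        for rep in range(20):
            members = rng.choice(ranking.index.to_numpy(), 10, replace=False)
            res = gsea_preranked(ranking, GeneSet.of("s", members),
                                 n_perm=100, seed=rep)
            nes.append(abs(res.nes))
        assert 0.7 < float(np.mean(nes)) < 1.4

    def test_agrees_with_external_gsea_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        scores = np.sort(rng.normal(size=50))[::-1]
        members = [genes[i] for i in (2, 7, 11, 23, 40)]
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets={"S": members}, permutation_num=10, seed=1,
            min_size=1, max_size=500, weight=1.0, outdir=None, no_plot=True,
        )
        external_es = float(res.res2d["ES"].iloc[0])
        mine = gsea_preranked(pd.Series(scores, index=genes),
                              GeneSet.of("S", members), n_perm=10, seed=1)
        assert mine.es == pytest.approx(external_es, abs=1e-9)

    def test_collection_applies_bh_and_size_bounds(self):
        rng = np.random.default_rng(14)
        ranking = pd.Series(np.sort(rng.normal(size=60))[::-1],
                            index=[f"g{i}" for i in range(60)])
        sets = [GeneSet.of("ok", [f"g{i}" for i in range(0, 12, 2)]),
                GeneSet.of("tiny", ["g3"])]
        df = gsea_preranked_collection(ranking, sets, n_perm=50, seed=1,
                                       set_size_bounds=(5, 500))
        assert list(df["gene_set"]) == ["ok"]
        assert (df["fdr"] >= df["p_value"] - 1e-12).all()


class TestSsgsea:
    def test_top_rank_placement_is_maximal_by_exhaustive_permutation(self):
        values = [9.0, 7.0, 5.0, 4.0, 3.0, 2.0]
        genes = [f"g{i}" for i in range(6)]
        gs = GeneSet.of("s", ["g0", "g1"])
        scores = []
        for k, perm in enumerate(itertools.permutations(values)):
            expr = pd.DataFrame({f"p{k:03d}": list(perm)}, index=genes)
            s = ssgsea_score(expr, gs, min_mean_expression=0, normalize=False)
            scores.append((float(s.iloc[0]), perm))
        best = max(scores)[1]
        # maximal score has the two set genes holding the two largest values
        assert {best[0], best[1]} == {9.0, 7.0}

    def test_uniformly_interleaved_set_scores_near_zero(self):
        genes = [f"g{i}" for i in range(40)]
        expr = pd.DataFrame({"s1": np.linspace(100, 1, 40)}, index=genes)
        interleaved = ssgsea_score(expr, GeneSet.of("s", genes[::4]),
                                   min_mean_expression=0, normalize=False)
        top = ssgsea_score(expr, GeneSet.of("s", genes[:10]),
                           min_mean_expression=0, normalize=False)
        assert abs(float(interleaved.iloc[0])) < 0.35 * float(top.iloc[0])

    def test_identical_samples_identical_scores(self):
        genes = [f"g{i}" for i in range(10)]
        col = np.linspace(50, 5, 10)
        expr = pd.DataFrame({"a": col, "b": col}, index=genes)
        s = ssgsea_score(expr, GeneSet.of("s", genes[:3]), min_mean_expression=0)
        assert s["a"] == s["b"]

    def test_invariant_under_monotone_transform_in_rank_only_mode(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(20)]
        expr = pd.DataFrame({"a": rng.uniform(1, 100, 20)}, index=genes)
        gs = GeneSet.of("s", genes[2:7])
        s1 = ssgsea_score(expr, gs, min_mean_expression=0, weight=0.0,
                          normalize=False)
        s2 = ssgsea_score(np.log(expr) * 3 + 1, gs, min_mean_expression=0,
                          weight=0.0, normalize=False)
        assert s1["a"] == pytest.approx(s2["a"], abs=1e-12)

    def test_expression_filter_can_empty_the_set(self):
        expr = pd.DataFrame({"a": [0.1, 50.0]}, index=["low", "high"])
        with pytest.raises(ValueError, match="vanished"):
            ssgsea_score(expr, GeneSet.of("s", ["low"]), min_mean_expression=1.0)


class TestCorrelations:
    def test_perfect_linear_relation(self):
        x = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        y = 2 * x + 1
        df = correlate_with_adjustment({"x": x}, {"y": y}, [("x", "y")])
        assert df["r"].iloc[0] == pytest.approx(1.0)
        assert df["q_value"].iloc[0] < 0.001

    def test_anticorrelated_regulator_target(self):
        rng = np.random.default_rng(16)
        x = pd.Series(rng.uniform(0, 1, 30), index=[f"s{i}" for i in range(30)])
        y = 1 - x + rng.normal(0, 0.02, 30)
        df = correlate_with_adjustment({"reg": x}, {"tgt": y}, [("reg", "tgt")])
        assert df["r"].iloc[0] < -0.9 and df["q_value"].iloc[0] < 0.001

    def test_null_pairs_bh_controls_discoveries(self):
        rng = np.random.default_rng(17)
        samples = [f"s{i}" for i in range(30)]
        x = {f"x{i}": pd.Series(rng.normal(size=30), index=samples)
             for i in range(200)}
        y = {f"y{i}": pd.Series(rng.normal(size=30), index=samples)
             for i in range(200)}
        pairs = [(f"x{i}", f"y{i}") for i in range(200)]
        df = correlate_with_adjustment(x, y, pairs)
        raw_rate = float((df["p_value"] < 0.05).mean())
        assert raw_rate < 0.12  # ~5% expected
        assert (df["q_value"] < 0.05).sum() <= 2

    def test_too_few_observations_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="fewer than 3"):
            correlate_with_adjustment({"x": x}, {"y": x}, [("x", "y")])


class TestCorrelatedTargetProportion:
    def test_single_perfectly_correlated_target(self):
        samples = [f"s{i}" for i in range(20)]
        reg = pd.DataFrame([np.linspace(0, 1, 20)], index=["R"], columns=samples)
        tgt = pd.DataFrame([np.linspace(0.2, 0.9, 20)], index=["T"],
                           columns=samples)
        prop = correlated_target_proportion(tgt, reg, include_all_mode=False)
        assert prop["R"] == 1.0

    def test_driven_vs_independent_targets(self):
        rng = np.random.default_rng(18)
        samples = [f"s{i}" for i in range(40)]
        reg_vals = rng.uniform(0.2, 0.8, 40)
        reg = pd.DataFrame([reg_vals, rng.uniform(0, 1, 40)],
                           index=["R1", "R2"], columns=samples)
        driven = np.clip(reg_vals[None, :] + rng.normal(0, 0.03, (15, 40)), 0, 1)
        tgt = pd.DataFrame(driven, index=[f"T{i}" for i in range(15)],
                           columns=samples)
        prop = correlated_target_proportion(tgt, reg)
        assert prop["R1"] > 0.9
        assert prop["R2"] < 0.3
        assert "All" in prop.index
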
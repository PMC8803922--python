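"""Entropy burden, driver alteration fractions, pathway status, comparisons."""
import math

import numpy as np
import pandas as pd
import pytest

from spliceburden.burden import (
    BurdenTable,
    assemble_burden_table,
    classify_pathway_status,
    compare_burdens,
    driver_mutation_burden,
    driver_splicing_burden,
    entropy_burden_series,
    gene_entropy,
    sample_splicing_burden,
)
from spliceburden.types import GeneSet, MutationCall


def _abundance_from_ratios(ratios, total=100.0):
    """One-sample abundance matrix realizing the given isoform ratios."""
    tids = [f"t{i}" for i in range(len(ratios))]
    ab = pd.DataFrame({"s1": [r * total for r in ratios]}, index=tids)
    return ab, {t: "G1" for t in tids}


class TestGeneEntropy:
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ((0.5, 0.5), math.log(2)),
            ((1.0, 0.0), 0.0),
            ((0.7, 0.2, 0.1),
             -(0.7 * math.log(0.7) + 0.2 * math.log(0.2) + 0.1 * math.log(0.1))),
        ],
    )
    def test_known_distributions(self, ratios, expected):
        ab, t2g = _abundance_from_ratios(ratios)
        rec = gene_entropy(ab, t2g, "G1", "s1")
        assert rec.H == pytest.approx(expected, abs=1e-12)
        assert rec.g == len(ratios)

    def test_low_abundance_gene_is_missing(self):
        ab, t2g = _abundance_from_ratios((0.5, 0.5), total=0.5)
        assert gene_entropy(ab, t2g, "G1", "s1", min_gene_abundance=1.0) is None

    def test_unknown_gene_rejected(self):
        ab, t2g = _abundance_from_ratios((0.5, 0.5))
        with pytest.raises(KeyError):
            gene_entropy(ab, t2g, "NOPE", "s1")

    def test_matches_brute_force_and_bounds_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            g = int(rng.integers(2, 7))
            ratios = rng.dirichlet(np.full(g, 0.6))
            ab, t2g = _abundance_from_ratios(ratios)
            rec = gene_entropy(ab, t2g, "G1", "s1")
            brute = -sum(p * math.log(p) for p in ratios if p > 0)
            assert rec.H == pytest.approx(brute, abs=1e-12)
            assert -1e-15 <= rec.H <= math.log(g) + 1e-9

    def test_uniform_ratios_attain_log_g(self):
        for g in (2, 3, 5):
            ab, t2g = _abundance_from_ratios([1.0 / g] * g)
            assert gene_entropy(ab, t2g, "G1", "s1").H == \
                pytest.approx(math.log(g), abs=1e-9)


class TestSampleBurden:
    def test_median_over_multi_isoform_genes(self):
        # three 2-isoform genes with distinct entropies; one single-isoform
        # gene that must be ignored
        frames, t2g = [], {}
        for i, ratios in enumerate([(1.0, 0.0), (0.9, 0.1), (0.5, 0.5), (1.0,)]):
            tids = [f"g{i}t{j}" for j in range(len(ratios))]
            frames.append(pd.DataFrame({"s1": [r * 50 for r in ratios]}, index=tids))
            t2g.update({t: f"G{i}" for t in tids})
        ab = pd.concat(frames)
        expected = float(np.median([0.0,
                                    -(0.9 * math.log(0.9) + 0.1 * math.log(0.1)),
                                    math.log(2)]))
        assert sample_splicing_burden(ab, t2g, "s1") == pytest.approx(expected)

    def test_all_uniform_two_isoform_genes_give_log2(self):
        frames, t2g = [], {}
        for i in range(4):
            tids = [f"g{i}a", f"g{i}b"]
            frames.append(pd.DataFrame({"s1": [30.0, 30.0]}, index=tids))
            t2g.update({t: f"G{i}" for t in tids})
        assert sample_splicing_burden(pd.concat(frames), t2g, "s1") == \
            pytest.approx(math.log(2), abs=1e-12)

    def test_no_qualifying_genes_returns_missing(self):
        ab = pd.DataFrame({"s1": [0.1, 0.1]}, index=["a", "b"])
        assert sample_splicing_burden(ab, {"a": "G1", "b": "G1"}, "s1",
                                      min_gene_abundance=1.0) is None


class TestDriverSplicingBurden:
    def _setup(self, tumor_psis):
        """One driver gene, one event; normal mean psi = 0.20."""
        cols = ["n1", "n2", "t1"]
        psi = pd.DataFrame([[0.15, 0.25, tumor_psis]], index=["e1"], columns=cols)
        return psi, {"GD": ["e1"]}, GeneSet.of("drivers", ["GD"])

    def test_change_above_threshold_is_altered(self):
        psi, ebg, drivers = self._setup(0.55)  # |0.55 - 0.20| = 0.35 > 0.30
        table = driver_splicing_burden(psi, ebg, ["n1", "n2"], ["t1"], drivers)
        assert table.per_sample.loc["t1", "driver_splice_fraction"] == 1.0

    def test_change_at_or_below_threshold_not_altered(self):
        psi, ebg, drivers = self._setup(0.45)  # 0.25 <= 0.30
        table = driver_splicing_burden(psi, ebg, ["n1", "n2"], ["t1"], drivers)
        assert table.per_sample.loc["t1", "driver_splice_fraction"] == 0.0

    def test_half_of_two_driver_genes_altered(self):
        cols = ["n1", "n2", "t1"]
        psi = pd.DataFrame([[0.2, 0.2, 0.9], [0.5, 0.5, 0.5]],
                           index=["e1", "e2"], columns=cols)
        table = driver_splicing_burden(
            psi, {"GA": ["e1"], "GB": ["e2"]}, ["n1", "n2"], ["t1"],
            GeneSet.of("d", ["GA", "GB"]),
        )
        assert table.per_sample.loc["t1", "driver_splice_fraction"] == 0.5

    def test_matches_brute_force_recount_on_random_fixture(self):
        rng = np.random.default_rng(9)
        normals = [f"n{i}" for i in range(5)]
        tumors = [f"t{i}" for i in range(8)]
        genes = [f"G{i}" for i in range(6)]
        events, ebg = [], {}
        for g in genes:
            ebg[g] = [f"{g}_e{k}" for k in range(rng.integers(1, 4))]
            events += ebg[g]
        psi = pd.DataFrame(rng.random((len(events), 13)), index=events,
                           columns=normals + tumors)
        psi[psi < 0.07] = np.nan  # sprinkle missingness
        table = driver_splicing_burden(psi, ebg, normals, tumors,
                                       GeneSet.of("d", genes), 0.30)
        # brute force: literal re-loop over genes/events/samples
        for t in tumors:
            altered = usable = 0
            for g in genes:
                devs = []
                for e in ebg[g]:
                    ref = np.nanmean(psi.loc[e, normals].to_numpy())
                    v = psi.loc[e, t]
                    if not np.isnan(ref) and not np.isnan(v):
                        devs.append(abs(v - ref))
                if devs:
                    usable += 1
                    altered += int(max(devs) > 0.30)
            got = table.per_sample.loc[t, "driver_splice_fraction"]
            if usable == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(altered / usable, abs=1e-12)

    def test_raising_threshold_never_increases_fractions(self):
        rng = np.random.default_rng(10)
        normals, tumors = ["n1", "n2", "n3"], ["t1", "t2", "t3", "t4"]
        events = [f"e{i}" for i in range(12)]
        ebg = {f"G{i}": events[2 * i: 2 * i + 2] for i in range(6)}
        psi = pd.DataFrame(rng.random((12, 7)), index=events,
                           columns=normals + tumors)
        drivers = GeneSet.of("d", list(ebg))
        prev = None
        for thr in (0.1, 0.2, 0.3, 0.5, 0.8):
            cur = driver_splicing_burden(psi, ebg, normals, tumors, drivers, thr)
            frac = cur.per_sample["driver_splice_fraction"]
            if prev is not None:
                assert (frac <= prev + 1e-12).all()
            prev = frac


class TestPathwayStatus:
    SET = GeneSet.of("ras", ["A", "B"])

    def test_qualifying_missense_makes_mutant(self):
        calls = [MutationCall("s1", "A", "SNV", "missense", 0.25, 50)]
        assert classify_pathway_status(calls, self.SET, "s1", ["A", "B"]).status \
            == "mutant"

    def test_cnv_gain_mutant_and_subthreshold_indeterminate(self):
        gain = [MutationCall("s1", "A", "CNV", copy_number=5)]
        assert classify_pathway_status(gain, self.SET, "s1", ["A", "B"]).status \
            == "mutant"
        # 4-copy gain plus a sub-threshold SNV: not qualifying, but the gene
        # is not alteration-free either
        mixed = [MutationCall("s1", "A", "CNV", copy_number=4),
                 MutationCall("s1", "B", "SNV", "missense", 0.1, 50)]
        assert classify_pathway_status(mixed, self.SET, "s1", ["A", "B"]).status \
            == "indeterminate"

    def test_homozygous_deletion_is_mutant(self):
        calls = [MutationCall("s1", "B", "CNV", copy_number=0)]
        assert classify_pathway_status(calls, self.SET, "s1", ["A", "B"]).status \
            == "mutant"

    def test_covered_and_clean_is_wild_type(self):
        assert classify_pathway_status([], self.SET, "s1", ["A", "B"]).status \
            == "wild_type"

    def test_uncovered_gene_blocks_wild_type(self):
        assert classify_pathway_status([], self.SET, "s1", ["A"]).status \
            == "indeterminate"


class TestMutationBurden:
    def test_two_hits_in_fifty_genes(self):
        genes = [f"G{i}" for i in range(50)]
        calls = [MutationCall("s1", "G0", "SNV", "nonsense", 0.4, 60),
                 MutationCall("s1", "G1", "CNV", copy_number=7)]
        table = driver_mutation_burden(calls, GeneSet.of("d", genes), ["s1"])
        assert table.per_sample.loc["s1", "driver_mutation_fraction"] == \
            pytest.approx(0.04)

    def test_no_calls_all_zero(self):
        table = driver_mutation_burden([], GeneSet.of("d", ["A", "B"]), ["s1", "s2"])
        assert (table.per_sample["driver_mutation_fraction"] == 0).all()
        assert (table.per_gene["mutated_sample_fraction"] == 0).all()

    def test_decoys_do_not_count(self):
        calls = [MutationCall("s1", "A", "SNV", "missense", 0.1, 100),  # low VAF
                 MutationCall("s1", "B", "SNV", "missense", 0.5, 10),  # low depth
                 MutationCall("s1", "A", "SNV", "other", 0.5, 100),  # low impact
                 MutationCall("s1", "B", "CNV", copy_number=4)]  # modest gain
        table = driver_mutation_burden(calls, GeneSet.of("d", ["A", "B"]), ["s1"])
        assert table.per_sample.loc["s1", "driver_mutation_fraction"] == 0.0

    def test_input_order_and_duplicate_invariance(self):
        genes = GeneSet.of("d", ["A", "B", "C"])
        calls = [MutationCall("s1", "A", "SNV", "missense", 0.4, 60),
                 MutationCall("s2", "C", "CNV", copy_number=6)]
        fwd = driver_mutation_burden(calls, genes, ["s1", "s2"])
        rev = driver_mutation_burden(calls[::-1] + calls, genes, ["s2", "s1"])
        pd.testing.assert_frame_equal(fwd.per_sample, rev.per_sample)


class TestCompareBurdens:
    def _table(self, splice, mut):
        per_sample = pd.DataFrame({
            "driver_splice_fraction": splice,
            "driver_mutation_fraction": mut,
        }, index=[f"s{i}" for i in range(len(splice))])
        return BurdenTable(per_sample, pd.DataFrame())

    def test_identical_vectors_give_null_result(self):
        t = self._table([0.2] * 5, [0.2] * 5)
        res = compare_burdens(t)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_swapping_arms_flips_sign_same_p(self):
        rng = np.random.default_rng(11)
        a = 0.3 + rng.normal(0, 0.02, 20)
        b = 0.05 + rng.normal(0, 0.02, 20)
        t_ab = self._table(a, b)
        t_ba = self._table(b, a)
        r1, r2 = compare_burdens(t_ab), compare_burdens(t_ba)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.p_value < 0.01 and r1.statistic > 0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            compare_burdens(self._table([0.1, 0.2], [0.1, 0.2]))


def test_entropy_burden_series_consistent_with_scalar(small_bundle):
    series = entropy_burden_series(small_bundle.abundance,
                                   small_bundle.transcript_to_gene)
    s = small_bundle.tumor_samples[0]
    scalar = sample_splicing_burden(small_bundle.abundance,
                                    small_bundle.transcript_to_gene, s)
    assert series[s] == pytest.approx(scalar, abs=1e-12)
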
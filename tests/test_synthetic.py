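"""Properties of the synthetic-cohort generator."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceburden import io as sb_io
from spliceburden.diffsplice import differential_events
from spliceburden.psi import psi_matrix
from spliceburden.synthetic import (
    CohortConfig,
    simulate_cohort,
    simulate_mutations,
    simulate_survival_times,
    write_bundle,
)
from spliceburden.types import GeneSet, is_qualifying


def _tiny(seed, **over):
    base = dict(seed=seed, n_tumor=12, n_normal=8, n_genes=40, n_events=60,
                n_driver_genes=12, pathway_size=10)
    base.update(over)
    return CohortConfig(**base)


class TestDeterminism:
    def test_same_seed_bitwise_identical_bundle(self):
        b1, b2 = simulate_cohort(_tiny(33)), simulate_cohort(_tiny(33))
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        pd.testing.assert_frame_equal(b1.abundance, b2.abundance)
        assert b1.mutations == b2.mutations
        assert [(r.sample_id, r.os_time, r.os_event) for r in b1.clinical] == \
               [(r.sample_id, r.os_time, r.os_event) for r in b2.clinical]

    def test_different_seeds_differ(self):
        b1, b2 = simulate_cohort(_tiny(33)), simulate_cohort(_tiny(34))
        assert not b1.counts.equals(b2.counts)

    def test_missing_seed_rejected(self):
        with pytest.raises((TypeError, ValueError)):
            CohortConfig(seed=None)


class TestEventCounts:
    def test_high_depth_low_dispersion_recovers_truth(self):
        cfg = _tiny(35, read_depth=10_000.0, overdispersion=0.0, n_events=40)
        bundle = simulate_cohort(cfg)
        psi = psi_matrix(bundle.events, bundle.counts)
        truth = bundle.event_truth.set_index("event_id")
        normals = bundle.normal_samples
        est = psi.loc[truth.index, normals].mean(axis=1)
        assert float((est - truth["psi_normal"]).abs().max()) < 0.02

    def test_zero_planted_fraction_yields_null_caller_output(self):
        cfg = _tiny(36, planted_fraction=0.0, n_events=150)
        bundle = simulate_cohort(cfg)
        psi = psi_matrix(bundle.events, bundle.counts)
        calls = differential_events(psi, bundle.tumor_samples,
                                    bundle.normal_samples)
        assert sum(c.significant for c in calls) <= max(2, 0.02 * len(calls))


class TestAbundances:
    def test_tumor_entropy_exceeds_normal_across_replicates(self):
        wins = 0
        for seed in range(10):
            bundle = simulate_cohort(_tiny(200 + seed))
            ent = bundle.entropy_truth
            t = ent[bundle.tumor_samples].mean(axis=None)
            n = ent[bundle.normal_samples].mean(axis=None)
            wins += int(t > n)
        assert wins >= 9

    def test_single_isoform_genes_absent_from_entropy_truth(self):
        bundle = simulate_cohort(_tiny(37))
        singletons = {g.gene_id for g in bundle.genes if len(g.transcripts) == 1}
        assert singletons.isdisjoint(set(bundle.entropy_truth.index))

    def test_nf1_ratio_positively_coupled_to_pathway_expression(self):
        bundle = simulate_cohort(_tiny(38))
        pathway_mean = bundle.expression.loc[
            sorted(bundle.pathway_set.genes)].mean(axis=0)
        joined = pd.concat([bundle.nf1_truth.rename("psi"),
                            pathway_mean.rename("expr")], axis=1).dropna()
        r, _ = stats.pearsonr(joined["psi"], np.log(joined["expr"]))
        assert r > 0.3


class TestMutations:
    def test_qualifying_fraction_tracks_probability(self):
        rng = np.random.default_rng(40)
        genes = GeneSet.of("d", [f"G{i}" for i in range(50)])
        samples = [f"T{i}" for i in range(60)]
        cfg = _tiny(41, mutation_prob=0.05, decoy_prob=0.0, cnv_gain_prob=0.0,
                    cnv_del_prob=0.0, cnv_neutralish_prob=0.0)
        calls = simulate_mutations(cfg, rng, samples, genes)
        frac = sum(is_qualifying(c) for c in calls) / (50 * 60)
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_zero_probability_means_no_calls(self):
        rng = np.random.default_rng(42)
        cfg = _tiny(43, mutation_prob=0.0, decoy_prob=0.0, cnv_gain_prob=0.0,
                    cnv_del_prob=0.0, cnv_neutralish_prob=0.0)
        assert simulate_mutations(cfg, rng, ["T1"],
                                  GeneSet.of("d", ["G1"])) == []

    def test_decoys_never_qualify(self):
        rng = np.random.default_rng(44)
        cfg = _tiny(45, mutation_prob=0.0, decoy_prob=1.0, cnv_gain_prob=0.0,
                    cnv_del_prob=0.0, cnv_neutralish_prob=0.0)
        calls = simulate_mutations(cfg, rng, [f"T{i}" for i in range(10)],
                                   GeneSet.of("d", [f"G{i}" for i in range(10)]))
        assert calls and not any(is_qualifying(c) for c in calls)


class TestSurvival:
    def test_no_censoring_means_all_events(self):
        cfg = _tiny(46, censor_rate=0.0)
        rng = np.random.default_rng(46)
        burden = pd.Series(np.linspace(0, 0.5, 20),
                           index=[f"T{i}" for i in range(20)])
        recs = simulate_survival_times(cfg, rng, burden)
        assert all(r.os_event == 1 for r in recs)

    def test_high_burden_shortens_survival(self):
        cfg = _tiny(47, censor_rate=0.0, log_hr_burden=4.0)
        lows, highs = [], []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            burden = pd.Series([0.0] * 50 + [0.5] * 50,
                               index=[f"T{i:03d}" for i in range(100)])
            recs = simulate_survival_times(cfg, rng, burden)
            times = pd.Series({r.sample_id: r.os_time for r in recs})
            lows.append(times.iloc[:50].median())
            highs.append(times.iloc[50:].median())
        wins = sum(h < l for l, h in zip(lows, highs))
        assert wins >= 9

    def test_null_burden_gives_uniformish_logrank_p(self):
        from spliceburden.survival import survival_test
        cfg = _tiny(48, censor_rate=0.0, log_hr_burden=0.0)
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(500 + seed)
            burden = pd.Series(rng.uniform(0, 0.5, 40),
                               index=[f"T{i:03d}" for i in range(40)])
            recs = simulate_survival_times(cfg, rng, burden)
            half = len(recs) // 2
            pvals.append(survival_test(recs[:half], recs[half:]).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.005


def test_written_bundle_passes_validation_and_round_trips(tmp_path):
    bundle = simulate_cohort(_tiny(49))
    write_bundle(bundle, tmp_path)
    psi = psi_matrix(bundle.events,
                     sb_io.read_event_counts(tmp_path / "event_counts.tsv"))
    abundance = sb_io.read_matrix(tmp_path / "abundance.tsv")
    mutations = sb_io.read_mutations(tmp_path / "mutations.tsv")
    clinical = sb_io.read_clinical(tmp_path / "clinical.tsv")
    report = sb_io.validate_bundle(psi=psi, abundance=abundance,
                                   mutations=mutations, clinical=clinical)
    assert report.ok
    # numeric round trip is exact
    assert np.array_equal(abundance.to_numpy(), bundle.abundance.to_numpy())
    cfg = CohortConfig.from_yaml(tmp_path / "config.yaml")
    assert cfg == bundle.config
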
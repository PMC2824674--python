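import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import themesurv as ts
from themesurv.cluster import first_test_prepared
from themesurv.null_model import (
    expected_exceedance,
    expected_false_positives,
    expected_outperformance,
)


def _null(values, **kw):
    values = np.asarray(values, dtype=float)
    defaults = dict(
        collection_tag="c", endpoint_tag="OS", sizes=np.full(values.size, 10),
        n_discarded=0, seed=0,
    )
    defaults.update(kw)
    return ts.EmpiricalNull(null_p1=values, **defaults)


class TestDrawRandomGeneset:
    universe = [f"g{i}" for i in range(200)]

    def test_full_universe(self):
        rng = np.random.default_rng(0)
        gs = ts.draw_random_geneset(self.universe, 200, rng)
        assert gs.genes == frozenset(self.universe)

    def test_unique_members_of_universe(self):
        rng = np.random.default_rng(1)
        gs = ts.draw_random_geneset(self.universe, 20, rng)
        assert len(gs.genes) == 20 and gs.genes <= set(self.universe)

    def test_seed_reproducibility(self):
        a = ts.draw_random_geneset(self.universe, 20, np.random.default_rng(7))
        b = ts.draw_random_geneset(self.universe, 20, np.random.default_rng(7))
        c = ts.draw_random_geneset(self.universe, 20, np.random.default_rng(8))
        assert a.genes == b.genes and a.genes != c.genes

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            ts.draw_random_geneset(self.universe, 201, np.random.default_rng(0))


class TestSizeSampler:
    def test_proportional_to_multiset(self):
        sampler = ts.SizeSampler(np.array([10, 10, 20]))
        rng = np.random.default_rng(3)
        draws = np.array([sampler.draw(rng) for _ in range(10_000)])
        frac10 = (draws == 10).mean()
        # 4-sigma binomial band around 2/3
        assert abs(frac10 - 2 / 3) < 4 * np.sqrt((2 / 3) * (1 / 3) / 10_000)

    def test_single_size_is_exact_mode(self):
        sampler = ts.SizeSampler(np.array([512]))
        rng = np.random.default_rng(0)
        assert sampler.size_mode == "exact"
        assert all(sampler.draw(rng) == 512 for _ in range(10))

    def test_from_tested_sets(self):
        sets = [ts.GeneSet(f"s{i}", "c", frozenset(f"g{j}" for j in range(n)))
                for i, n in enumerate([5, 8, 8])]
        sampler = ts.make_size_sampler(None, sets)
        assert sorted(sampler.sizes_multiset) == [5, 8, 8]
        with pytest.raises(ValueError):
            ts.make_size_sampler(None, [])


class TestEmpiricalP2:
    def test_four_of_a_thousand(self):
        # 4 null values at or below p1 -> p2 = 4/1000 = 0.004
        vals = np.concatenate([[0.001, 0.002, 0.003, 0.004], np.linspace(0.01, 0.99, 996)])
        assert ts.empirical_p2(0.004, _null(vals)) == 0.004

    def test_p1_of_one_gives_one(self):
        assert ts.empirical_p2(1.0, _null(np.linspace(0.01, 0.99, 50))) == 1.0

    def test_p1_below_all_gives_zero(self):
        assert ts.empirical_p2(1e-6, _null(np.linspace(0.01, 0.99, 50))) == 0.0

    def test_ties_counted_inclusively(self):
        assert ts.empirical_p2(0.5, _null([0.5, 0.5, 0.9, 0.9])) == 0.5

    def test_pseudocount_variant(self):
        n = _null(np.linspace(0.01, 0.99, 999))
        assert ts.empirical_p2(0.0, n, pseudocount=True) == pytest.approx(1 / 1000)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_on_grid(self, pool, a, b):
        n = _null(pool)
        lo, hi = min(a, b), max(a, b)
        p_lo, p_hi = ts.empirical_p2(lo, n), ts.empirical_p2(hi, n)
        assert p_lo <= p_hi
        assert p_lo * n.B == pytest.approx(round(p_lo * n.B))


class TestBhFdr:
    def test_constant_vector_is_fixed_point(self):
        np.testing.assert_allclose(ts.bh_fdr([0.2] * 7), 0.2)

    def test_hand_stepup_example(self):
        # min over the tail of p_(i) * m / i: all collapse to 0.04
        np.testing.assert_allclose(ts.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(ts.bh_fdr([0.33]), 0.33)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                ts.bh_fdr(p), sm.multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_p_and_rank_monotone(self, p):
        adj = ts.bh_fdr(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestBuildEmpiricalNull:
    def test_same_seed_bit_identical(self, null_dataset):
        _, prep, universe = null_dataset
        sampler = ts.SizeSampler(np.array([10, 25]))
        n1 = ts.build_empirical_null(universe, sampler, prep, B=50, seed=5)
        n2 = ts.build_empirical_null(universe, sampler, prep, B=50, seed=5)
        np.testing.assert_array_equal(n1.null_p1, n2.null_p1)
        np.testing.assert_array_equal(n1.sizes, n2.sizes)
        assert n1.n_discarded == n2.n_discarded

    def test_prefix_nesting(self, null_dataset):
        _, prep, universe = null_dataset
        sampler = ts.SizeSampler(np.array([15]))
        big = ts.build_empirical_null(universe, sampler, prep, B=80, seed=5)
        small = ts.build_empirical_null(universe, sampler, prep, B=30, seed=5)
        np.testing.assert_array_equal(big.null_p1[:30], small.null_p1)

    def test_aborts_when_everything_discarded(self, null_dataset):
        _, prep, _ = null_dataset
        # universe of unmapped genes: every draw fails the probe filter
        bogus = [f"zz{i}" for i in range(100)]
        sampler = ts.SizeSampler(np.array([10]))
        with pytest.raises(RuntimeError, match="discarded"):
            ts.build_empirical_null(bogus, sampler, prep, B=10, seed=0)

    def test_serialization_roundtrip(self, null_dataset, tmp_path):
        _, prep, universe = null_dataset
        sampler = ts.SizeSampler(np.array([10, 25]))
        null = ts.build_empirical_null(
            universe, sampler, prep, B=40, seed=5,
            collection_tag="demo", endpoint_tag="OS",
        )
        ts.save_empirical_null(null, tmp_path / "null")
        back = ts.load_empirical_null(tmp_path / "null")
        np.testing.assert_array_equal(back.null_p1, null.null_p1)
        np.testing.assert_array_equal(back.sizes, null.sizes)
        assert (back.collection_tag, back.endpoint_tag) == ("demo", "OS")
        assert back.n_discarded == null.n_discarded and back.seed == null.seed


class TestSecondTest:
    cfg = ts.PipelineConfig(B=100, seed=0)

    def _first(self, name, p1):
        return ts.FirstTestResult(name, 10, 12, cluster_sizes=(5, 10), logrank_statistic=1.0, p1=p1)

    def test_p1_below_every_null_value_flagged(self):
        null = _null(np.linspace(0.1, 0.9, 100))
        recs = ts.second_test([self._first("winner", 0.001)], null, self.cfg)
        assert recs[0].p2 == 0.0 and recs[0].p2 < self.cfg.alpha

    def test_identical_p1_identical_p2_and_fdr(self):
        null = _null(np.linspace(0.01, 0.99, 100))
        firsts = [self._first(f"g{i}", 0.2) for i in range(5)]
        recs = ts.second_test(firsts, null, self.cfg)
        assert len({r.p2 for r in recs}) == 1
        assert len({r.fdr1 for r in recs}) == 1 and len({r.fdr2 for r in recs}) == 1

    def test_discarded_results_carried_through(self):
        null = _null(np.linspace(0.01, 0.99, 100))
        firsts = [
            self._first("ok", 0.3),
            ts.FirstTestResult("bad", 3, status="discarded", discard_reason="too_few_genes"),
        ]
        recs = ts.second_test(firsts, null, self.cfg)
        assert recs[1].status == "discarded" and recs[1].p2 is None

    def test_tag_mismatch_rejected(self):
        null = _null(np.linspace(0.01, 0.99, 100), collection_tag="GO-like")
        with pytest.raises(ValueError, match="GO-like"):
            ts.second_test([self._first("g", 0.5)], null, self.cfg, collection_tag="KEGG-like")

    def test_summary_counts(self):
        null = _null(np.linspace(0.001, 0.999, 1000))
        firsts = [self._first("sig", 0.0005), self._first("ns", 0.5)]
        recs = ts.second_test(firsts, null, self.cfg)
        s = ts.summarize_results(recs, self.cfg)
        assert s["n_tested"] == 2
        assert s["p1_significant"] == 1 and s["p2_significant"] == 1


class TestUniformityDiagnostics:
    def test_evenly_spaced_grid_has_minimal_ks(self):
        B = 500
        grid = (np.arange(B) + 0.5) / B
        d = ts.uniformity_diagnostics(_null(grid))
        assert d.ks_statistic <= 1 / (2 * B) + 1e-9
        assert not d.uniform_rejected

    def test_degenerate_mass_rejected(self):
        d = ts.uniformity_diagnostics(_null(np.full(100, 0.01)))
        assert d.ks_statistic == pytest.approx(0.99, abs=1e-9)
        assert d.uniform_rejected

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        d = ts.uniformity_diagnostics(_null(rng.random(1000)))
        widths = d.density["bin_right"] - d.density["bin_left"]
        assert (d.density["density"] * widths).sum() == pytest.approx(1.0)
        assert len(d.qq) == 1000

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            ts.uniformity_diagnostics(_null([0.5] * 5))


class TestSizeEffectScan:
    def test_oversized_scan_skipped(self, null_dataset):
        _, prep, universe = null_dataset
        table, discards = ts.size_effect_scan(
            universe, prep, sizes=(10, 10_000), reps_per_size=5, seed=0
        )
        assert set(table["size"]) == {10}
        assert 10_000 not in discards

    def test_same_seed_identical(self, null_dataset):
        _, prep, universe = null_dataset
        t1, _ = ts.size_effect_scan(universe, prep, sizes=(10,), reps_per_size=20, seed=4)
        t2, _ = ts.size_effect_scan(universe, prep, sizes=(10,), reps_per_size=20, seed=4)
        np.testing.assert_array_equal(t1["p1"], t2["p1"])

    def test_noise_data_median_neglog10_near_uniform_value(self, null_dataset):
        # -log10 of a Uniform(0,1) median is log10(2) ~ 0.301
        _, prep, universe = null_dataset
        table, _ = ts.size_effect_scan(universe, prep, sizes=(15,), reps_per_size=400, seed=8)
        assert abs(table["neg_log10_p1"].median() - np.log10(2)) < 0.15


class TestStability:
    def test_reference_self_concordance(self, null_dataset):
        ds, prep, universe = null_dataset
        sampler = ts.SizeSampler(np.array([15]))
        sets = [ts.draw_random_geneset(universe, 15, np.random.default_rng(s), name=f"t{s}")
                for s in range(6)]
        tab = ts.stability_analysis(
            universe, sampler, prep, B_list=(100, 300), reference_B=300,
            genesets=sets, seed=2,
        )
        ref_row = tab[tab["B"] == 300].iloc[0]
        assert ref_row["max_abs_delta_p2"] == 0.0
        assert ref_row["pearson_r_neglog10_p2"] == pytest.approx(1.0)
        small_row = tab[tab["B"] == 100].iloc[0]
        assert small_row["max_abs_delta_p2"] <= 0.25

    def test_same_seed_identical_table(self, null_dataset):
        _, prep, universe = null_dataset
        sampler = ts.SizeSampler(np.array([15]))
        sets = [ts.draw_random_geneset(universe, 15, np.random.default_rng(3), name="t")]
        t1 = ts.stability_analysis(universe, sampler, prep, B_list=(50, 100), genesets=sets, seed=2)
        t2 = ts.stability_analysis(universe, sampler, prep, B_list=(50, 100), genesets=sets, seed=2)
        assert t1.equals(t2)


def test_competitive_arithmetic_helpers():
    assert expected_outperformance(0.004, 1000) == pytest.approx(996.0)
    assert expected_exceedance(0.004, 1000) == pytest.approx(4.0)
    assert expected_false_positives(1082, 0.01) == pytest.approx(10.82)
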
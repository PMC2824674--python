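import math

import numpy as np
import pandas as pd
import pytest

import themesurv as ts
from themesurv.cluster import (
    DistanceMatrix,
    average_linkage_two_way_split,
    correlation_distance,
    first_test_prepared,
    pairwise_correlation_distance,
)
from themesurv.preprocess import GenesetExclusion


def _matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ts.ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        col = np.array([1.0, 2.0, 3.0, 5.0])
        m = _matrix(np.column_stack([col, col]))
        dm = correlation_distance(m)
        assert isinstance(dm, DistanceMatrix)
        assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_distance_two(self):
        col = np.array([1.0, 2.0, 3.0, 5.0])
        m = _matrix(np.column_stack([col, -col]))
        dm = correlation_distance(m)
        assert dm.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        # x=(1,2,3,4), y=(1,3,2,5): rho = 22/sqrt(700) by the textbook formula
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        dm = correlation_distance(_matrix(np.column_stack([x, y])))
        rho = 22 / math.sqrt(700)
        assert dm.d[0, 1] == pytest.approx(1 - rho, abs=1e-12)

    def test_pairwise_complete_uses_shared_probes_only(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, np.nan])
        dm = correlation_distance(_matrix(np.column_stack([x, y])))
        assert dm.d[0, 1] == pytest.approx(1 - 22 / math.sqrt(700), abs=1e-12)

    def test_too_few_complete_pairs_is_exclusion(self):
        x = [1.0, 2.0, np.nan, np.nan]
        y = [1.0, np.nan, 2.0, 3.0]  # only 1 shared probe
        out = correlation_distance(_matrix(np.column_stack([x, y])))
        assert isinstance(out, GenesetExclusion)
        assert out.reason == "undefined_distance"

    def test_zero_variance_is_exclusion(self):
        x = [1.0, 1.0, 1.0, 1.0]
        y = [1.0, 2.0, 3.0, 4.0]
        out = correlation_distance(_matrix(np.column_stack([x, y])))
        assert isinstance(out, GenesetExclusion)

    def test_matrix_is_symmetric_zero_diagonal_in_range(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((15, 8))
        vals[rng.random((15, 8)) < 0.2] = np.nan
        d = pairwise_correlation_distance(vals)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        ok = np.isfinite(d)
        assert d[ok].min() >= 0.0 and d[ok].max() <= 2.0


class TestTwoWaySplit:
    def test_hand_computed_upgma_root_split(self):
        # A-B merge at 1, C-D at 2, root joins them at mean(8,9,8.5,9.5)=8.75
        d = np.array(
            [
                [0.0, 1.0, 8.0, 9.0],
                [1.0, 0.0, 8.5, 9.5],
                [8.0, 8.5, 0.0, 2.0],
                [9.0, 9.5, 2.0, 0.0],
            ]
        )
        labels = average_linkage_two_way_split(d)
        assert labels.tolist() == [1, 1, 2, 2]

    def test_two_tight_blobs_recovered(self):
        rng = np.random.default_rng(4)
        a = np.array([2.0, -1.0, 0.5, 1.5, -2.0, 0.0, 1.0, -0.5])
        b = -a
        cols = [a + 0.05 * rng.standard_normal(8) for _ in range(5)]
        cols += [b + 0.05 * rng.standard_normal(8) for _ in range(5)]
        dm = correlation_distance(_matrix(np.column_stack(cols)))
        labels = average_linkage_two_way_split(dm)
        assert labels.tolist() == [1] * 5 + [2] * 5

    def test_two_samples(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert average_linkage_two_way_split(d).tolist() == [1, 2]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_two_way_split(np.zeros((1, 1)))

    def test_labels_invariant_to_probe_order(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((20, 12))
        d1 = pairwise_correlation_distance(vals)
        d2 = pairwise_correlation_distance(vals[rng.permutation(20)])
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        assert (
            average_linkage_two_way_split(d1).tolist()
            == average_linkage_two_way_split(d2).tolist()
        )


class TestLogRank:
    def test_hand_tabulated_ledger(self):
        # group A events at t=1,2; group B at t=3,4; all observed.
        # O-E = 7/6, V = 1/4 + 2/9 = 17/36, statistic = 49/17.
        labels = np.array([1, 1, 2, 2])
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        stat, p = ts.logrank_test(labels, times, events)
        assert stat == pytest.approx(49 / 17, abs=1e-12)
        assert p == pytest.approx(math.erfc(math.sqrt(stat / 2)), rel=1e-12)

    def test_mirror_image_groups_give_statistic_zero(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        events = np.ones(6, dtype=int)
        stat, p = ts.logrank_test(labels, times, events)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_symmetric_in_group_labels(self):
        labels = np.array([1, 1, 2, 2])
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        s1, p1 = ts.logrank_test(labels, times, events)
        s2, p2 = ts.logrank_test(3 - labels, times, events)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_no_events_warns_and_returns_one(self):
        stat, p = ts.logrank_test(
            np.array([1, 2, 1, 2]), np.array([1.0, 2, 3, 4]), np.zeros(4, dtype=int)
        )
        assert (stat, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ts.logrank_test(np.array([1, 1]), np.array([1.0, 2.0]), np.array([1, 1]))


def _blob_dataset(n_a, n_b, seed=0, n_probes=12):
    """Two clearly separated sample blobs of given sizes + probe map."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n_probes) * 2
    cols = [base + 0.1 * rng.standard_normal(n_probes) for _ in range(n_a)]
    cols += [-base + 0.1 * rng.standard_normal(n_probes) for _ in range(n_b)]
    n = n_a + n_b
    m = _matrix(np.column_stack(cols), probes=[f"p{i}" for i in range(n_probes)])
    pm = ts.ProbeMap({f"g{i}": frozenset({f"p{i}"}) for i in range(n_probes)})
    clin = ts.ClinicalTable(
        "OS",
        pd.DataFrame(
            {"time": rng.exponential(1.0, n), "event": rng.integers(0, 2, n)},
            index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
        ),
    )
    return m, pm, clin


class TestFirstTest:
    cfg = ts.PreprocessConfig()

    def test_uneven_clusters_discarded(self):
        # 4 of 51 in the smaller cluster: 4/51 < 0.10
        m, pm, clin = _blob_dataset(4, 47)
        g = ts.GeneSet("gs", "c", frozenset(f"g{i}" for i in range(12)))
        res = ts.first_test(g, m, pm, clin, self.cfg)
        assert res.status == "discarded" and res.discard_reason == "uneven_clusters"
        assert sorted(res.cluster_sizes) == [4, 47]

    def test_evenness_boundary_proceeds(self):
        # 6 of 51: 6/51 ~ 0.118 >= 0.10 -> log-rank runs
        m, pm, clin = _blob_dataset(6, 45)
        g = ts.GeneSet("gs", "c", frozenset(f"g{i}" for i in range(12)))
        res = ts.first_test(g, m, pm, clin, self.cfg)
        assert res.ok and 0 <= res.p1 <= 1
        assert sorted(res.cluster_sizes) == [6, 45]

    def test_strong_survival_axis_gives_small_p1(self):
        spec = ts.SimulationSpec(
            n_genes=300, n_samples=60, fraction_affected=0.5, shift=2.0,
            hazard_ratio=5.0, missing_rate=0.0, replicate_rate=0.0, seed=21,
        )
        ds = ts.gen_confounded_dataset(spec)
        m = ts.preprocess_matrix(ds.expression, self.cfg)
        prep = ts.prepare_dataset(m, ds.probe_map, ds.clinical, self.cfg)
        genes = sorted(ds.probe_map.mapping)[:30]
        res = first_test_prepared(prep, "axis", genes)
        assert res.ok and res.p1 < 0.01

    def test_deterministic(self, null_dataset):
        _, prep, universe = null_dataset
        genes = universe[:20]
        r1 = first_test_prepared(prep, "g", genes)
        r2 = first_test_prepared(prep, "g", genes)
        assert r1.p1 == r2.p1 and r1.logrank_statistic == r2.logrank_statistic
        assert r1.labels.tolist() == r2.labels.tolist()
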
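"""Partial correlation, Fisher-z testing, PC skeleton, and orientation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanoqsar.causal import (
    fisher_z_test,
    orient_edges,
    partial_correlation,
    pc_skeleton,
    run_causal_analysis,
)
from nanoqsar.synthetic import DagSpec, gen_dag


@pytest.fixture(scope="module")
def chain_data():
    spec = DagSpec(
        nodes=("X", "Y", "Z"), edges={("X", "Y"): 1.0, ("Y", "Z"): 1.0}, n=2000, seed=3
    )
    return gen_dag(spec)


@pytest.fixture(scope="module")
def collider_data():
    spec = DagSpec(
        nodes=("X", "Y", "Z"), edges={("X", "Z"): 1.0, ("Y", "Z"): 1.0}, n=2000, seed=5
    )
    return gen_dag(spec)


class TestPartialCorrelation:
    def test_empty_set_reduces_to_pearson(self, rng):
        frame = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        expected = stats.pearsonr(frame["a"], frame["b"]).statistic
        assert partial_correlation(frame, "a", "b") == pytest.approx(expected)

    def test_identical_columns_fully_correlated(self, rng):
        a = rng.normal(size=100)
        frame = pd.DataFrame({"a": a, "b": a})
        assert partial_correlation(frame, "a", "b") == pytest.approx(1.0)

    def test_chain_screens_off(self, chain_data):
        data, _ = chain_data
        assert partial_correlation(data, "X", "Z", ("Y",)) == pytest.approx(0.0, abs=0.05)

    def test_collinear_conditioning_named(self, rng):
        a = rng.normal(size=50)
        frame = pd.DataFrame({"a": a, "b": rng.normal(size=50), "c": a, "d": 2 * a})
        with pytest.raises(ValueError, match="singular"):
            partial_correlation(frame, "a", "b", ("c", "d"))

    def test_sample_size_guard(self, rng):
        frame = pd.DataFrame(rng.normal(size=(3, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="n >"):
            partial_correlation(frame, "a", "b", ("c",))


class TestFisherZ:
    def test_zero_correlation_max_p(self):
        statistic, p, independent = fisher_z_test(0.0, 100, 0, alpha=0.05)
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert independent

    def test_closed_form_example(self):
        statistic, p, _ = fisher_z_test(0.5, 30, 1, alpha=0.05)
        assert statistic == pytest.approx(math_sqrt26_times_z(), abs=0.001)
        assert p == pytest.approx(0.0051, abs=0.0005)

    def test_perfect_correlation_tiny_p(self):
        _, p, independent = fisher_z_test(0.999999, 50, 0, alpha=0.05)
        assert p < 1e-12
        assert not independent

    def test_insufficient_sample_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_test(0.3, 5, 2)


def math_sqrt26_times_z():
    import math

    return math.sqrt(26) * 0.5 * math.log(1.5 / 0.5)


class TestSkeleton:
    def test_independent_columns_empty_skeleton(self, rng):
        frame = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        graph, _ = pc_skeleton(frame, alpha=0.05)
        assert graph.edge_count() == 0
        assert frozenset(("a", "b")) in graph.sepsets

    def test_chain_skeleton(self, chain_data):
        data, _ = chain_data
        graph, log = pc_skeleton(data, alpha=0.05)
        edges = {tuple(sorted(p)) for p in graph.undirected}
        assert edges == {("X", "Y"), ("Y", "Z")}
        assert graph.sepsets[frozenset(("X", "Z"))] == ("Y",)
        assert all(0 <= t.p_value <= 1 for t in log)

    def test_perfectly_correlated_pair_retained(self, rng):
        a = rng.normal(size=200)
        frame = pd.DataFrame({"a": a, "b": a + 1e-9 * rng.normal(size=200)})
        graph, _ = pc_skeleton(frame, alpha=0.05)
        assert graph.edge_count() == 1

    def test_order_independence(self, chain_data):
        data, _ = chain_data
        g1, _ = pc_skeleton(data, alpha=0.05)
        permuted = data[["Z", "X", "Y"]]
        g2, _ = pc_skeleton(permuted, alpha=0.05)
        assert {tuple(sorted(p)) for p in g1.undirected} == {
            tuple(sorted(p)) for p in g2.undirected
        }
        assert g1.sepsets == g2.sepsets

    def test_alpha_monotonicity(self, collider_data):
        data, _ = collider_data
        strict, _ = pc_skeleton(data, alpha=0.001)
        loose, _ = pc_skeleton(data, alpha=0.2)
        assert strict.undirected <= loose.undirected


class TestOrientation:
    def test_collider_oriented(self, collider_data):
        data, truth = collider_data
        graph, _ = pc_skeleton(data, alpha=0.05)
        cpdag = orient_edges(graph)
        assert cpdag.edges_as_tuples() == truth.edges_as_tuples()
        assert ("X", "Z") in cpdag.directed and ("Y", "Z") in cpdag.directed

    def test_chain_stays_undirected(self, chain_data):
        data, truth = chain_data
        graph, _ = pc_skeleton(data, alpha=0.05)
        cpdag = orient_edges(graph)
        assert cpdag.edges_as_tuples() == truth.edges_as_tuples()
        assert not cpdag.directed

    def test_empty_skeleton_empty_cpdag(self, rng):
        frame = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        graph, _ = pc_skeleton(frame, alpha=0.01)
        cpdag = orient_edges(graph)
        assert cpdag.edge_count() == graph.edge_count()


class TestRunAnalysis:
    def test_small_group_reports_insufficient(self, rng):
        frame = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        results = run_causal_analysis(frame, groups={"tiny": [0, 1, 2]})
        assert results["tiny"].graph is None
        assert results["tiny"].note == "insufficient n"

    def test_small_sample_warning_attached(self, rng):
        frame = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="below a reliable regime"):
            results = run_causal_analysis(frame)
        assert results["pooled"].note is not None

    def test_size_driven_activity_recovers_edge(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(900 + seed)
            size = rng.uniform(240, 840, 500)
            noise = rng.normal(0, 0.05, 500)
            frame = pd.DataFrame(
                {
                    "size": size,
                    "other": rng.uniform(0, 1, 500),
                    "activity": 1.3 - 0.0006 * size + noise,
                }
            )
            graph, _ = pc_skeleton(frame, alpha=0.05)
            edges = {tuple(sorted(p)) for p in graph.undirected}
            if edges == {("activity", "size")}:
                hits += 1
        assert hits >= 23  # >= 90 % of 25 seeds
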
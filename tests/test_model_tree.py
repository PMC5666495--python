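"""M5 model-tree growth, leaf models, pruning, smoothing, and importance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nanoqsar.model_tree import (
    Hyperparams,
    LinearLeafModel,
    ModelTree,
    Node,
    fit_leaf_models,
    grow_tree,
    predict,
    prune,
    relative_importance,
    sdr,
)
from nanoqsar.synthetic import PiecewiseSpec, gen_piecewise
from nanoqsar.validation import fit_m5p


class TestSdr:
    def test_pure_separation_equals_parent_sd(self):
        parent = [1, 1, 1, 5, 5, 5]
        value = sdr(parent, ([1, 1, 1], [5, 5, 5]))
        assert value == pytest.approx(math.sqrt(4.8), abs=1e-3)  # 2.191

    def test_constant_targets_give_zero(self):
        assert sdr([3, 3, 3, 3], ([3, 3], [3, 3])) == pytest.approx(0.0)

    def test_singleton_children_contribute_zero_sd(self):
        assert sdr([0, 2], ([0], [2])) == pytest.approx(math.sqrt(2), abs=1e-3)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            sdr([1, 2], ([], [1, 2]))
        with pytest.raises(ValueError):
            sdr([1, 2, 3], ([1], [2]))


def brute_force_best_split(x, y, min_side):
    """Exhaustive SDR argmax over midpoints of one attribute (oracle)."""
    order = np.argsort(x, kind="stable")
    xs, ys = np.asarray(x, float)[order], np.asarray(y, float)[order]
    best = None
    for pos in range(len(xs) - 1):
        if xs[pos] == xs[pos + 1]:
            continue
        if pos + 1 < min_side or len(xs) - pos - 1 < min_side:
            continue
        threshold = (xs[pos] + xs[pos + 1]) / 2
        value = sdr(ys, (ys[: pos + 1], ys[pos + 1 :]))
        if best is None or value > best[0]:
            best = (value, threshold)
    return best


class TestGrow:
    def test_split_matches_bruteforce_oracle_on_small_batteries(self):
        """Chosen root split equals exhaustive SDR argmax, all n <= 8 datasets."""
        rng = np.random.default_rng(202)
        batteries = []
        for n in range(2, 9):
            for _ in range(8):
                batteries.append(
                    (rng.integers(0, 5, size=n).astype(float), rng.normal(size=n))
                )
        for min_inst in (1, 2):
            hp = Hyperparams(min_instances=min_inst, sd_fraction=0.0)
            for x, y in batteries:
                if len(x) < 2 * min_inst or np.std(y, ddof=1) == 0:
                    continue
                tree = grow_tree(x.reshape(-1, 1), y, hp, attributes=("x",))
                oracle = brute_force_best_split(x, y, min_inst)
                root = tree.root
                if oracle is None or oracle[0] <= 0:
                    assert root.is_leaf
                else:
                    assert not root.is_leaf
                    assert root.threshold == pytest.approx(oracle[1])
                    assert root.split_sdr == pytest.approx(oracle[0])

    def test_constant_target_single_leaf(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        tree = grow_tree(X, np.full(20, 7.0))
        assert tree.root.is_leaf

    def test_noiseless_line_collapses_to_single_linear_leaf(self):
        x = np.linspace(0, 1, 50)
        X = pd.DataFrame({"x": x})
        tree = fit_m5p(X, 3 * x)
        assert tree.root.is_leaf
        model = tree.root.model
        coef = dict(zip(model.attributes, model.coefficients))
        assert coef.get("x", 0.0) == pytest.approx(3.0, abs=1e-6)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_piecewise_breakpoint_recovered(self):
        spec = PiecewiseSpec(
            n=200,
            attributes=("x",),
            split_attribute="x",
            breakpoints=(0.5,),
            segment_models=({"x": 1.0, "intercept": 0.0}, {"x": -1.0, "intercept": 10.0}),
            noise_sd=0.05,
            seed=7,
        )
        X, y, _ = gen_piecewise(spec)
        tree = grow_tree(X, y)
        assert tree.root.split_attribute == "x"
        assert 0.45 <= tree.root.threshold <= 0.55

    def test_leaf_minimum_respected(self, rng):
        X = pd.DataFrame({"a": rng.uniform(size=60), "b": rng.uniform(size=60)})
        y = rng.normal(size=60)
        tree = grow_tree(X, y, Hyperparams(min_instances=4))
        assert all(leaf.n_train >= 4 for leaf in tree.leaves())

    def test_determinism_bit_for_bit(self, rng):
        X = pd.DataFrame(rng.uniform(size=(80, 3)), columns=["a", "b", "c"])
        y = (X["a"] > 0.5).astype(float) + rng.normal(0, 0.1, 80)
        t1 = fit_m5p(X, y)
        t2 = fit_m5p(X.copy(), y.copy())
        assert t1.to_json() == t2.to_json()


class TestLeafModels:
    def test_constant_leaf_intercept_only(self):
        X = pd.DataFrame({"x": np.arange(5.0)})
        y = np.full(5, 2.5)
        tree = grow_tree(X, y)
        fit_leaf_models(tree, X, y)
        model = tree.root.model
        assert model.attributes == ()
        assert model.intercept == pytest.approx(2.5)

    def test_noiseless_two_attribute_ols_exact(self, rng):
        X = pd.DataFrame({"a": rng.uniform(size=30), "b": rng.uniform(size=30)})
        y = 2 * X["a"].to_numpy() - X["b"].to_numpy()
        tree = grow_tree(X, y, Hyperparams(min_instances=30))  # single node
        fit_leaf_models(tree, X, y, whitelist=("a", "b"))
        coef = dict(zip(tree.root.model.attributes, tree.root.model.coefficients))
        assert coef["a"] == pytest.approx(2.0, abs=1e-8)
        assert coef["b"] == pytest.approx(-1.0, abs=1e-8)

    def test_constant_attribute_excluded(self, rng):
        X = pd.DataFrame({"a": rng.uniform(size=20), "b": np.ones(20)})
        y = X["a"].to_numpy() * 4.0
        tree = grow_tree(X, y, Hyperparams(min_instances=20))
        fit_leaf_models(tree, X, y, whitelist=("a", "b"))
        assert "b" not in tree.root.model.attributes

    def test_collinear_column_dropped_deterministically(self, rng):
        a = rng.uniform(size=25)
        X = pd.DataFrame({"a": a, "b": 2 * a})  # b collinear with a
        y = 3 * a
        tree = grow_tree(X, y, Hyperparams(min_instances=25))
        fit_leaf_models(tree, X, y, whitelist=("a", "b"))
        assert "b" not in tree.root.model.attributes  # first-listed kept


class TestPrune:
    def test_single_leaf_unchanged(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = np.full(10, 1.0)
        tree = grow_tree(X, y)
        fit_leaf_models(tree, X, y)
        before = tree.to_json()
        prune(tree, X, y)
        assert tree.to_json() == before

    def test_pure_noise_prunes_to_single_leaf_mostly(self):
        collapsed = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.uniform(size=(100, 3)), columns=["a", "b", "c"])
            y = rng.normal(size=100)
            tree = fit_m5p(X, y)
            collapsed += tree.root.is_leaf
        assert collapsed >= 45  # >= 90 % of 50 seeds

    def test_noiseless_piecewise_structure_preserved(self):
        spec = PiecewiseSpec(
            n=200,
            attributes=("x",),
            split_attribute="x",
            breakpoints=(0.5,),
            segment_models=({"x": 1.0, "intercept": 0.0}, {"x": -1.0, "intercept": 10.0}),
            noise_sd=0.0,
            seed=11,
        )
        X, y, _ = gen_piecewise(spec)
        tree = fit_m5p(X, y)
        assert not tree.root.is_leaf
        assert tree.root.split_attribute == "x"


def _manual_two_leaf_tree(k=15.0, root_slope=0.0, root_intercept=0.5):
    left = Node(
        n_train=10,
        model=LinearLeafModel(attributes=(), coefficients=np.zeros(0), intercept=0.0, n_train=10),
    )
    right = Node(
        n_train=10,
        model=LinearLeafModel(attributes=(), coefficients=np.zeros(0), intercept=1.0, n_train=10),
    )
    root = Node(
        n_train=20,
        split_attribute="x",
        threshold=0.5,
        left=left,
        right=right,
        model=LinearLeafModel(
            attributes=("x",),
            coefficients=np.asarray([root_slope]),
            intercept=root_intercept,
            n_train=20,
        ),
    )
    return ModelTree(attributes=("x",), root=root, hyperparams=Hyperparams(smoothing_k=k))


class TestPredict:
    def test_two_leaf_smoothing_formula(self):
        tree = _manual_two_leaf_tree(k=15.0, root_slope=0.2, root_intercept=0.3)
        x = {"x": 0.8}  # routes to leaf with constant 1, n=10
        q_root = 0.3 + 0.2 * 0.8
        expected = (10 * 1.0 + 15 * q_root) / 25
        assert tree.predict_row(x, smoothed=True) == pytest.approx(expected)
        assert tree.predict_row(x, smoothed=False) == pytest.approx(1.0)

    def test_zero_smoothing_constant_is_identity(self):
        tree = _manual_two_leaf_tree(k=0.0, root_slope=0.7)
        assert tree.predict_row({"x": 0.1}, smoothed=True) == pytest.approx(
            tree.predict_row({"x": 0.1}, smoothed=False)
        )

    def test_identical_path_models_make_smoothing_a_noop(self):
        tree = _manual_two_leaf_tree(k=15.0, root_slope=0.0, root_intercept=1.0)
        # right leaf predicts 1.0 and the root model is the constant 1.0
        assert tree.predict_row({"x": 0.9}, smoothed=True) == pytest.approx(1.0)

    def test_missing_attribute_named(self):
        tree = _manual_two_leaf_tree()
        with pytest.raises(KeyError, match="x"):
            tree.predict_row({"y": 1.0})

    def test_module_level_predict_delegates(self):
        tree = _manual_two_leaf_tree(k=0.0)
        assert predict(tree, {"x": 0.2}) == pytest.approx(0.0)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, rng):
        X = pd.DataFrame(rng.uniform(size=(60, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() + (X["b"] > 0.5) * 2.0 + rng.normal(0, 0.05, 60)
        tree = fit_m5p(X, y)
        clone = ModelTree.from_json(tree.to_json())
        grid = rng.uniform(size=(20, 2))
        np.testing.assert_allclose(
            tree.predict(grid), clone.predict(grid), rtol=0, atol=1e-12
        )

    def test_render_text_shows_split_and_models(self):
        tree = _manual_two_leaf_tree()
        text = tree.render_text()
        assert "x <= 0.5" in text and "LM:" in text


class TestRelativeImportance:
    def test_single_split_attribute_gets_everything(self, rng):
        x = np.sort(rng.uniform(size=40))
        X = pd.DataFrame({"a": x, "b": np.zeros(40)})
        y = (x > 0.5).astype(float) * 5
        tree = grow_tree(X, y)
        fit_leaf_models(tree, X, y)
        ri = relative_importance(tree)
        assert ri["a"] == pytest.approx(100.0)
        assert ri.sum() == pytest.approx(100.0, abs=0.01)

    def test_sums_to_one_hundred(self, rng):
        X = pd.DataFrame(rng.uniform(size=(120, 3)), columns=["a", "b", "c"])
        y = (X["a"] > 0.4) * 2 + X["b"] + rng.normal(0, 0.1, 120)
        tree = fit_m5p(X, y)
        ri = relative_importance(tree)
        assert ri.sum() == pytest.approx(100.0, abs=0.01)
        assert (ri >= 0).all()

    def test_single_leaf_intercept_only_uniform_with_warning(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)[::-1]})
        y = np.full(10, 3.0)
        tree = grow_tree(X, y)
        fit_leaf_models(tree, X, y)
        with pytest.warns(UserWarning, match="uniform"):
            ri = relative_importance(tree)
        assert ri["a"] == pytest.approx(50.0)
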
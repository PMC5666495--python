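"""M5 model-tree regression.

A model tree recursively partitions the feature space by axis-aligned
splits chosen to maximise the standard-deviation reduction (SDR) of the
target,

    SDR = sd(T) - sum_i |T_i|/|T| * sd(T_i),

and places an ordinary-least-squares linear model in every node.  After
growth the tree is pruned bottom-up by comparing each internal node's
model against its subtree, both scored with the M5 adjusted error
``err * (n + v) / (n - v)`` (``v`` = number of fitted parameters), and
predictions are smoothed along the root path,

    p' = (n * p + k * q) / (n + k),

where ``p`` is the prediction passed up from the node below (``n`` training
rows), ``q`` the current node's own model value, and ``k`` the smoothing
constant.

Conventions (they change thresholds, so they are spelled out):

* sample (n-1) standard deviation throughout; a child of size 1
  contributes sd = 0;
* candidate thresholds are midpoints of adjacent observed values, and both
  children of an admissible split must hold at least ``min_instances`` rows
  (the leaf minimum);
* growth stops when a node has fewer than ``2 * min_instances`` rows or its
  target sd falls below ``sd_fraction`` of the root sd;
* ties in SDR are broken toward the earlier column, then the smaller
  threshold;
* node models use the attributes occurring in splits of the node's subtree
  plus an optional caller-supplied whitelist; collinear columns are dropped
  deterministically (first-listed kept); terms are then greedily removed
  while the adjusted error decreases.

Relative importance (RI) of an attribute is its share of n-weighted SDR
summed over the splits made on it, normalised to 100 %.  Attributes that
never split but appear in leaf models receive a share derived from their
n-weighted standardised leaf coefficients, scaled into the split total.
For a bagged ensemble the per-tree RI vectors are averaged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Hyperparams",
    "LinearLeafModel",
    "Node",
    "ModelTree",
    "sdr",
    "grow_tree",
    "fit_leaf_models",
    "prune",
    "predict",
    "relative_importance",
]


@dataclass(frozen=True)
class Hyperparams:
    """M5 hyperparameters; defaults are the canonical M5/M5P settings."""

    min_instances: int = 4
    sd_fraction: float = 0.05
    smoothing_k: float = 15.0

    def __post_init__(self) -> None:
        if self.min_instances < 1:
            raise ValueError("min_instances must be >= 1")
        if not 0 <= self.sd_fraction < 1:
            raise ValueError("sd_fraction must be in [0, 1)")
        if self.smoothing_k < 0:
            raise ValueError("smoothing_k must be >= 0")


def _sd(values: np.ndarray) -> float:
    """Sample standard deviation; 0 for fewer than two values."""
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def sdr(parent_targets: Sequence[float], partition: tuple[Sequence[float], Sequence[float]]) -> float:
    """Standard-deviation reduction of splitting ``parent_targets`` into two sides.

    Raises
    ------
    ValueError
        If either side is empty or the partition does not cover the parent.
    """
    left, right = (np.asarray(side, dtype=float) for side in partition)
    parent = np.asarray(parent_targets, dtype=float)
    if len(left) < 1 or len(right) < 1:
        raise ValueError("each side of the partition needs at least one element")
    if len(left) + len(right) != len(parent):
        raise ValueError("partition does not cover the parent targets")
    n = len(parent)
    return _sd(parent) - (len(left) * _sd(left) + len(right) * _sd(right)) / n


@dataclass
class LinearLeafModel:
    """Affine model ``intercept + coefficients . attributes`` at a node."""

    attributes: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    n_train: int
    #: sd of each attribute over the node's training rows (for standardised RI).
    attr_scale: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.attributes):
            raise ValueError("coefficients and attributes must have equal length")

    def predict_vector(self, x: np.ndarray, attr_index: Mapping[str, int]) -> float:
        value = self.intercept
        for name, coef in zip(self.attributes, self.coefficients):
            value += coef * x[attr_index[name]]
        return float(value)


@dataclass
class Node:
    """Split node (with children) or leaf; every node carries a model after fitting."""

    n_train: int
    split_attribute: str | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    model: LinearLeafModel | None = None
    split_sdr: float | None = None
    # training-row indices; retained so model fitting and pruning can reuse them
    indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class ModelTree:
    """A fitted (or growing) M5 model tree over named attributes."""

    attributes: tuple[str, ...]
    root: Node
    hyperparams: Hyperparams

    # -- structure ---------------------------------------------------------
    def nodes(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def leaves(self) -> list[Node]:
        return [n for n in self.nodes() if n.is_leaf]

    def depth(self) -> int:
        def _depth(node: Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_depth(node.left), _depth(node.right))

        return _depth(self.root)

    def route(self, x: np.ndarray) -> list[Node]:
        """Root-to-leaf path for one feature vector."""
        index = {a: i for i, a in enumerate(self.attributes)}
        path = [self.root]
        node = self.root
        while not node.is_leaf:
            node = node.left if x[index[node.split_attribute]] <= node.threshold else node.right
            path.append(node)
        return path

    # -- prediction --------------------------------------------------------
    def _coerce_row(self, x) -> np.ndarray:
        if isinstance(x, Mapping) or isinstance(x, pd.Series):
            missing = [a for a in self.attributes if a not in x]
            if missing:
                raise KeyError(f"feature vector is missing attribute(s) {missing}")
            return np.asarray([float(x[a]) for a in self.attributes])
        arr = np.asarray(x, dtype=float)
        if arr.shape != (len(self.attributes),):
            raise ValueError(
                f"expected a vector of {len(self.attributes)} attributes, got shape {arr.shape}"
            )
        return arr

    def predict_row(self, x, smoothed: bool = True) -> float:
        arr = self._coerce_row(x)
        index = {a: i for i, a in enumerate(self.attributes)}
        path = self.route(arr)
        leaf = path[-1]
        if leaf.model is None:
            raise RuntimeError("tree has no leaf models; call fit_leaf_models first")
        value = leaf.model.predict_vector(arr, index)
        if not smoothed or self.hyperparams.smoothing_k == 0:
            return value
        k = self.hyperparams.smoothing_k
        for ancestor, child in zip(path[-2::-1], path[:0:-1]):
            if ancestor.model is None:
                continue
            q = ancestor.model.predict_vector(arr, index)
            value = (child.n_train * value + k * q) / (child.n_train + k)
        return value

    def predict(self, X, smoothed: bool = True) -> np.ndarray:
        X = _coerce_matrix(X, self.attributes)
        return np.asarray([self.predict_row(row, smoothed=smoothed) for row in X])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def encode(node: Node) -> dict:
            out: dict = {"n_train": node.n_train}
            if node.model is not None:
                out["model"] = {
                    "attributes": list(node.model.attributes),
                    "coefficients": [float(c) for c in node.model.coefficients],
                    "intercept": float(node.model.intercept),
                    "n_train": node.model.n_train,
                    "attr_scale": [float(s) for s in node.model.attr_scale],
                }
            if not node.is_leaf:
                out.update(
                    split_attribute=node.split_attribute,
                    threshold=float(node.threshold),
                    split_sdr=float(node.split_sdr) if node.split_sdr is not None else None,
                    left=encode(node.left),
                    right=encode(node.right),
                )
            return out

        return {
            "attributes": list(self.attributes),
            "hyperparams": {
                "min_instances": self.hyperparams.min_instances,
                "sd_fraction": self.hyperparams.sd_fraction,
                "smoothing_k": self.hyperparams.smoothing_k,
            },
            "root": encode(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelTree":
        def decode(obj: dict) -> Node:
            model = None
            if "model" in obj:
                m = obj["model"]
                model = LinearLeafModel(
                    attributes=tuple(m["attributes"]),
                    coefficients=np.asarray(m["coefficients"], dtype=float),
                    intercept=float(m["intercept"]),
                    n_train=int(m["n_train"]),
                    attr_scale=tuple(m.get("attr_scale", ())),
                )
            node = Node(n_train=int(obj["n_train"]), model=model)
            if "split_attribute" in obj:
                node.split_attribute = obj["split_attribute"]
                node.threshold = float(obj["threshold"])
                node.split_sdr = obj.get("split_sdr")
                node.left = decode(obj["left"])
                node.right = decode(obj["right"])
            return node

        hp = payload["hyperparams"]
        return cls(
            attributes=tuple(payload["attributes"]),
            root=decode(payload["root"]),
            hyperparams=Hyperparams(
                min_instances=int(hp["min_instances"]),
                sd_fraction=float(hp["sd_fraction"]),
                smoothing_k=float(hp["smoothing_k"]),
            ),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ModelTree":
        return cls.from_dict(json.loads(text))

    def render_text(self) -> str:
        """Human-readable nested rendering of splits and leaf models."""
        lines: list[str] = []

        def fmt_model(model: LinearLeafModel | None) -> str:
            if model is None:
                return "<unfitted>"
            terms = [f"{model.intercept:+.4g}"]
            terms += [
                f"{c:+.4g}*{a}" for a, c in zip(model.attributes, model.coefficients)
            ]
            return " ".join(terms) + f"  (n={model.n_train})"

        def walk(node: Node, indent: int) -> None:
            pad = "    " * indent
            if node.is_leaf:
                lines.append(f"{pad}LM: {fmt_model(node.model)}")
            else:
                lines.append(f"{pad}{node.split_attribute} <= {node.threshold:g} :")
                walk(node.left, indent + 1)
                lines.append(f"{pad}{node.split_attribute} >  {node.threshold:g} :")
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _coerce_matrix(X, attributes: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        if attributes is not None:
            missing = [a for a in attributes if a not in X.columns]
            if missing:
                raise KeyError(f"feature matrix is missing attribute(s) {missing}")
            X = X.loc[:, list(attributes)]
        return X.to_numpy(dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("feature matrix must be 2-dimensional")
    return arr


def _resolve_xy(X, y, attributes: Sequence[str] | None):
    if isinstance(X, pd.DataFrame) and attributes is None:
        attributes = tuple(str(c) for c in X.columns)
    arr = _coerce_matrix(X, attributes)
    if attributes is None:
        attributes = tuple(f"x{i}" for i in range(arr.shape[1]))
    targets = np.asarray(y, dtype=float)
    if targets.shape != (arr.shape[0],):
        raise ValueError("y must be one value per row of X")
    if np.isnan(arr).any() or np.isnan(targets).any():
        raise ValueError("missing values are not supported")
    return arr, targets, tuple(attributes)


def _best_split(X: np.ndarray, y: np.ndarray, idx: np.ndarray, min_side: int):
    """Argmax-SDR split over all attributes and admissible midpoints.

    Returns ``(sdr_value, attr_j, threshold, left_idx, right_idx)`` or None.
    Ties prefer the earlier attribute, then the smaller threshold (the first
    maximum encountered wins; candidates are scanned in that order).
    """
    parent_sd = _sd(y[idx])
    n = len(idx)
    best = None
    for j in range(X.shape[1]):
        column = X[idx, j]
        order = np.argsort(column, kind="stable")
        sorted_idx = idx[order]
        sorted_vals = column[order]
        for pos in range(n - 1):
            if sorted_vals[pos] == sorted_vals[pos + 1]:
                continue
            left_n = pos + 1
            right_n = n - left_n
            if left_n < min_side or right_n < min_side:
                continue
            threshold = 0.5 * (sorted_vals[pos] + sorted_vals[pos + 1])
            left = sorted_idx[:left_n]
            right = sorted_idx[left_n:]
            value = parent_sd - (left_n * _sd(y[left]) + right_n * _sd(y[right])) / n
            if best is None or value > best[0]:
                best = (value, j, threshold, left, right)
    return best


def grow_tree(X, y, hyperparams: Hyperparams | None = None, attributes=None) -> ModelTree:
    """Grow an unpruned model tree (structure only; no models fitted yet).

    ``X`` may be a DataFrame (column names become attribute names) or a 2-D
    array with an optional ``attributes`` sequence.
    """
    hyperparams = hyperparams or Hyperparams()
    arr, targets, names = _resolve_xy(X, y, attributes)
    if arr.shape[0] < 1:
        raise ValueError("at least one training row is required")
    root_sd = _sd(targets)
    min_inst = hyperparams.min_instances

    def build(idx: np.ndarray) -> Node:
        node = Node(n_train=len(idx), indices=idx)
        node_sd = _sd(targets[idx])
        if len(idx) < 2 * min_inst or node_sd < hyperparams.sd_fraction * root_sd:
            return node
        best = _best_split(arr, targets, idx, min_inst)
        if best is None or best[0] <= 0:
            return node
        value, j, threshold, left, right = best
        node.split_attribute = names[j]
        node.threshold = float(threshold)
        node.split_sdr = float(value)
        node.left = build(left)
        node.right = build(right)
        return node

    root = build(np.arange(arr.shape[0]))
    return ModelTree(attributes=names, root=root, hyperparams=hyperparams)


# -- node models -----------------------------------------------------------

def _subtree_split_attrs(node: Node) -> set[str]:
    if node.is_leaf:
        return set()
    return (
        {node.split_attribute}
        | _subtree_split_attrs(node.left)
        | _subtree_split_attrs(node.right)
    )


def _adjusted_error(residual_mae: float, n: int, v: int) -> float:
    """M5 adjusted error ``err * (n+v)/(n-v)``; infinite when n <= v."""
    if n <= v:
        return float("inf")
    return residual_mae * (n + v) / (n - v)


def _ols(Xn: np.ndarray, yn: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares with intercept; returns (coefficients, intercept)."""
    design = np.column_stack([Xn, np.ones(len(yn))])
    solution, *_ = np.linalg.lstsq(design, yn, rcond=None)
    return solution[:-1], float(solution[-1])


def _fit_node_model(
    node: Node,
    X: np.ndarray,
    y: np.ndarray,
    names: tuple[str, ...],
    whitelist: Sequence[str] | None,
) -> LinearLeafModel:
    idx = node.indices
    yn = y[idx]
    candidates = _subtree_split_attrs(node)
    if whitelist:
        candidates |= set(whitelist)
    # column order of the training matrix, for determinism
    ordered = [a for a in names if a in candidates]
    name_to_col = {a: i for i, a in enumerate(names)}
    # exclude attributes constant over the node's rows
    ordered = [a for a in ordered if _sd(X[idx, name_to_col[a]]) > 0]
    # deterministic collinearity handling: keep columns that raise the rank
    kept: list[str] = []
    for a in ordered:
        trial = np.column_stack(
            [X[idx][:, [name_to_col[b] for b in kept + [a]]], np.ones(len(idx))]
        )
        if np.linalg.matrix_rank(trial) > len(kept) + 1:
            kept.append(a)

    def fit(attrs: list[str]) -> tuple[LinearLeafModel, float]:
        if attrs:
            coefs, intercept = _ols(X[idx][:, [name_to_col[a] for a in attrs]], yn)
            pred = X[idx][:, [name_to_col[a] for a in attrs]] @ coefs + intercept
        else:
            coefs, intercept = np.zeros(0), float(np.mean(yn))
            pred = np.full(len(idx), intercept)
        mae = float(np.mean(np.abs(yn - pred)))
        err = _adjusted_error(mae, len(idx), len(attrs) + 1)
        model = LinearLeafModel(
            attributes=tuple(attrs),
            coefficients=coefs,
            intercept=intercept,
            n_train=len(idx),
            attr_scale=tuple(_sd(X[idx, name_to_col[a]]) for a in attrs),
        )
        return model, err

    model, err = fit(kept)
    # greedy term dropping while the adjusted error estimate decreases
    current = list(kept)
    while current:
        best_drop = None
        for a in current:
            trial_model, trial_err = fit([b for b in current if b != a])
            if best_drop is None or trial_err < best_drop[2]:
                best_drop = (a, trial_model, trial_err)
        if best_drop is not None and best_drop[2] < err:
            current.remove(best_drop[0])
            model, err = best_drop[1], best_drop[2]
        else:
            break
    return model


def fit_leaf_models(tree: ModelTree, X, y, whitelist: Sequence[str] | None = None) -> ModelTree:
    """Fit linear models at every node of a tree grown on the same (X, y).

    Each node's model uses the attributes occurring in splits of its subtree
    plus the optional ``whitelist`` (leaves therefore default to
    intercept-only models), simplified greedily under the M5 adjusted error.
    Internal-node models are retained for smoothing and pruning.
    """
    arr, targets, names = _resolve_xy(X, y, tree.attributes)
    if tree.root.indices is None:
        raise ValueError("tree does not carry training indices; regrow it on this data")
    for node in tree.nodes():
        node.model = _fit_node_model(node, arr, targets, names, whitelist)
    return tree


#: Extra weight on the parameter count in the pruning penalty
#: ``err * (n + PRUNING_MULTIPLIER * v) / (n - v)``, following the classic
#: M5 software lineage.  Without it, trees grown on pure noise retain most
#: of their structure (the in-sample gain of an SDR-optimal split on noise
#: exceeds the unweighted penalty).
PRUNING_MULTIPLIER = 2.0


def prune(tree: ModelTree, X, y) -> ModelTree:
    """Bottom-up M5 pruning: collapse a subtree when its node model is no worse.

    Both candidates are scored on the node's own training rows by the
    penalised root-mean-square error
    ``rmse * (n + PRUNING_MULTIPLIER * v) / (n - v)``.  For the node model,
    ``v`` is its coefficient count plus intercept; for the subtree, ``v``
    aggregates every leaf model's parameters plus one per split threshold.
    Deep structure fitted to noise is penalised away while genuine structure
    (whose raw error is far smaller than the node model's) survives.
    """
    arr, targets, names = _resolve_xy(X, y, tree.attributes)
    index = {a: i for i, a in enumerate(names)}
    # scale for the "model is essentially exact" prune clause below
    target_scale = _sd(targets) or 1.0

    def leaf_value(node: Node, row: np.ndarray) -> float:
        while not node.is_leaf:
            node = node.left if row[index[node.split_attribute]] <= node.threshold else node.right
        return node.model.predict_vector(row, index)

    def n_params(node: Node) -> int:
        if node.is_leaf:
            return len(node.model.attributes) + 1
        return 1 + n_params(node.left) + n_params(node.right)

    def adjusted(node: Node, as_subtree: bool) -> float:
        idx = node.indices
        if as_subtree:
            pred = np.asarray([leaf_value(node, arr[i]) for i in idx])
            v = n_params(node)
        else:
            pred = np.asarray([node.model.predict_vector(arr[i], index) for i in idx])
            v = len(node.model.attributes) + 1
        n = len(idx)
        if n <= v:
            return float("inf")
        error = float(np.sqrt(np.mean((targets[idx] - pred) ** 2)))
        return error * (n + PRUNING_MULTIPLIER * v) / (n - v)

    def walk(node: Node) -> None:
        if node.model is None:
            raise RuntimeError("fit_leaf_models must run before prune")
        if node.is_leaf:
            return
        walk(node.left)
        walk(node.right)
        own = adjusted(node, as_subtree=False)
        # a node model that is exact up to float noise always wins the tie
        if own <= adjusted(node, as_subtree=True) or own < 1e-10 * target_scale:
            node.left = node.right = None
            node.split_attribute = None
            node.threshold = None
            node.split_sdr = None

    walk(tree.root)
    return tree


def predict(tree: ModelTree, x, smoothed: bool = True) -> float:
    """Predict one feature vector (mapping, Series, or array in column order)."""
    return tree.predict_row(x, smoothed=smoothed)


# -- relative importance ---------------------------------------------------

def _single_tree_ri(tree: ModelTree) -> dict[str, float]:
    n_root = tree.root.n_train
    split_mass = {a: 0.0 for a in tree.attributes}
    any_split = False
    for node in tree.nodes():
        if not node.is_leaf and node.split_sdr is not None:
            split_mass[node.split_attribute] += (node.n_train / n_root) * node.split_sdr
            any_split = True
    coef_mass = {a: 0.0 for a in tree.attributes}
    for leaf in tree.leaves():
        if leaf.model is None:
            continue
        for a, c, s in zip(
            leaf.model.attributes, leaf.model.coefficients, leaf.model.attr_scale
        ):
            coef_mass[a] += (leaf.n_train / n_root) * abs(c) * s
    if not any_split:
        if all(mass == 0.0 for mass in coef_mass.values()):
            warnings.warn(
                "single-leaf tree with an intercept-only model: "
                "relative importance is uniform by convention"
            )
            k = len(tree.attributes)
            return {a: 100.0 / k for a in tree.attributes}
        total = sum(coef_mass.values())
        return {a: 100.0 * m / total for a, m in coef_mass.items()}
    total_split = sum(split_mass.values())
    never_split = [a for a in tree.attributes if split_mass[a] == 0.0]
    total_coef = sum(coef_mass.values())
    mass = dict(split_mass)
    if total_coef > 0:
        # attributes absent from every split inherit a share proportional to
        # their standardised leaf-coefficient mass, scaled into the split total
        for a in never_split:
            mass[a] = total_split * (coef_mass[a] / total_coef)
    total = sum(mass.values())
    return {a: 100.0 * m / total for a, m in mass.items()}


def relative_importance(model: ModelTree | Iterable[ModelTree], X=None, y=None) -> pd.Series:
    """Relative importance (percent, summing to 100) per attribute.

    ``model`` is a fitted :class:`ModelTree` or an iterable of them (a bagged
    ensemble), in which case per-tree percentages are averaged.
    """
    if isinstance(model, ModelTree):
        trees = [model]
    else:
        trees = list(model)
        if not trees:
            raise ValueError("empty ensemble")
    attributes = trees[0].attributes
    acc = np.zeros(len(attributes))
    for tree in trees:
        if tree.attributes != attributes:
            raise ValueError("ensemble trees disagree on attributes")
        ri = _single_tree_ri(tree)
        acc += np.asarray([ri[a] for a in attributes])
    acc /= len(trees)
    acc *= 100.0 / acc.sum()
    return pd.Series(acc, index=list(attributes), name="relative_importance")
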
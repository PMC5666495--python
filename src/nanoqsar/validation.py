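"""Fit statistics, dataset splitting, bagging validation, and outlier flags.

Two determination-coefficient variants are implemented because the study
prints a non-standard formula:

* ``variant="printed"``: ``R^2 = sum(yhat - ybar)^2 / sum(y - ybar)^2`` —
  the explained-to-total sum-of-squares ratio as printed; it can exceed 1
  for predictions that are not an OLS fit on the same data;
* ``variant="standard"``: ``1 - sum(y - yhat)^2 / sum(y - ybar)^2`` — the
  conventional definition, used for out-of-bag and external predictions.

Both agree (to rounding) for an intercept-included OLS fit evaluated on its
own training data.  RMSE follows the printed convention with an ``m - 1``
denominator.  Out-of-bag Q^2 uses the standard variant.

Bagging draws are without replacement at a configurable fraction of the
training set (default 60 %, matching the study's stated coverage);
classical same-size with-replacement bootstrap sampling is available via a
flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from nanoqsar.dataset_io import Dataset, parse_formula
from nanoqsar.model_tree import (
    Hyperparams,
    ModelTree,
    fit_leaf_models,
    grow_tree,
    prune,
)

__all__ = [
    "ValidationReport",
    "BaggingResult",
    "r_squared",
    "adjusted_r2",
    "rmse",
    "split_by_ranging",
    "fit_m5p",
    "bagging_validate",
    "flag_outliers",
    "pearson_r",
    "poly_r2",
]


def r_squared(y, yhat, variant: str = "standard") -> float:
    """Coefficient of determination; see the module docstring for variants."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be equal-length vectors of length >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("observed values are all equal; R^2 undefined")
    if variant == "printed":
        return float(np.sum((yhat - y.mean()) ** 2)) / tss
    if variant == "standard":
        return 1.0 - float(np.sum((y - yhat) ** 2)) / tss
    raise ValueError(f"unknown variant {variant!r}")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 for ``n`` rows and ``p`` predictors."""
    if n <= p + 1:
        raise ValueError("adjusted R^2 requires n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rmse(y, yhat) -> float:
    """Root-mean-square error with the study's ``m - 1`` denominator."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or len(y) < 2:
        raise ValueError("rmse requires equal-length vectors with m >= 2")
    return math.sqrt(float(np.sum((yhat - y) ** 2)) / (len(y) - 1))


def pearson_r(x, y) -> float:
    """Product-moment correlation of two nonconstant samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("pearson_r requires equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r is undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)


def poly_r2(x, y, degree: int) -> float:
    """Standard-variant R^2 of the least-squares polynomial of given degree.

    A saturated fit (``len(x) == degree + 1``) returns 1.0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 1:
        raise ValueError("not enough points for the requested degree")
    if len(x) == degree + 1:
        warnings.warn("saturated polynomial fit: R^2 is 1 by construction")
        return 1.0
    coeffs = np.polyfit(x, y, degree)
    return r_squared(y, np.polyval(coeffs, x), variant="standard")


def flag_outliers(y, yhat, labels=None) -> list:
    """Records whose |residual| exceeds 3 sample sd of all residuals.

    The residual sd includes the candidate itself ("three-sigma deviation
    for the developed model").  Returns flagged labels (indices if no labels
    are given).
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) < 3:
        raise ValueError("flag_outliers requires m >= 3")
    residuals = y - yhat
    sigma = float(np.std(residuals, ddof=1))
    if labels is None:
        labels = list(range(len(y)))
    if sigma == 0:  # identical residuals: no record deviates from the rest
        return []
    return [lab for lab, res in zip(labels, residuals) if abs(res) > 3 * sigma]


# -- dataset splitting -----------------------------------------------------

def stoichiometry_class(formula: str) -> str:
    """MeO / Me2O3 / MeO2 class from the cation:O ratio; otherwise "other"."""
    comp = parse_formula(formula)
    oxygen = comp.get("O", 0)
    metal = sum(v for k, v in comp.items() if k != "O")
    if metal == 0 or oxygen == 0:
        return "other"
    ratio = (metal, oxygen)
    g = math.gcd(metal, oxygen)
    ratio = (metal // g, oxygen // g)
    return {(1, 1): "MeO", (2, 3): "Me2O3", (1, 2): "MeO2", (3, 4): "other"}.get(
        ratio, "other"
    )


def split_by_ranging(dataset: Dataset, test_fraction: float) -> dict[str, str]:
    """Assign subset labels by ranging activity, covering stoichiometry classes.

    Records are sorted by activity; every ``ceil(1/test_fraction)``-th record
    (starting mid-stride) goes to the test set.  Deterministic swaps then
    ensure every stoichiometry class with at least two members appears in
    both subsets; single-member classes are left where they fall, with a
    warning.  Returns ``{record_id: "train"|"test"}``.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    records = list(dataset)
    if test_fraction == 0:
        return {r.record_id: "train" for r in records}
    stride = math.ceil(1.0 / test_fraction)
    ranked = sorted(records, key=lambda r: (r.activity, r.record_id))
    labels = {
        r.record_id: ("test" if i % stride == stride // 2 else "train")
        for i, r in enumerate(ranked)
    }
    target_test = sum(1 for v in labels.values() if v == "test")
    classes = {r.record_id: stoichiometry_class(r.formula) for r in records}

    def class_side_counts(side: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rid, lab in labels.items():
            if lab == side:
                counts[classes[rid]] = counts.get(classes[rid], 0) + 1
        return counts

    for cls in sorted(set(classes.values())):
        members = [r for r in ranked if classes[r.record_id] == cls]
        if len(members) < 2:
            warnings.warn(
                f"stoichiometry class {cls!r} has a single member; "
                "coverage constraint relaxed"
            )
            continue
        present = {labels[r.record_id] for r in members}
        if present == {"train"}:
            # move the member whose activity is most central to the test side
            labels[members[len(members) // 2].record_id] = "test"
        elif present == {"test"}:
            labels[members[0].record_id] = "train"
    # deterministic rebalance back to the stride count, never emptying a class
    while sum(1 for v in labels.values() if v == "test") > target_test:
        counts = class_side_counts("test")
        movable = [
            r for r in ranked
            if labels[r.record_id] == "test" and counts[classes[r.record_id]] > 1
        ]
        if not movable:
            break
        labels[movable[0].record_id] = "train"
    while sum(1 for v in labels.values() if v == "test") < target_test:
        counts = class_side_counts("train")
        movable = [
            r for r in ranked
            if labels[r.record_id] == "train" and counts[classes[r.record_id]] > 1
        ]
        if not movable:
            break
        labels[movable[0].record_id] = "test"
    return labels


# -- model fitting pipeline ------------------------------------------------

DESCRIPTOR_ATTRIBUTES = ("hydro_size", "density", "rwz", "ci")


def fit_m5p(
    X,
    y,
    hyperparams: Hyperparams | None = None,
    whitelist=None,
) -> ModelTree:
    """Grow, fit node models, and prune an M5 tree in one call."""
    tree = grow_tree(X, y, hyperparams)
    fit_leaf_models(tree, X, y, whitelist=whitelist)
    prune(tree, X, y)
    return tree


@dataclass
class ValidationReport:
    """Fit statistics for one data subset."""

    label: str
    m: int
    r2: float
    r2_printed: float | None
    r2_adj: float | None
    rmse: float
    outliers: list = field(default_factory=list)


def make_report(label, y, yhat, n_predictors=None, labels=None) -> ValidationReport:
    r2 = r_squared(y, yhat, variant="standard")
    try:
        r2p = r_squared(y, yhat, variant="printed")
    except ValueError:
        r2p = None
    r2a = None
    if n_predictors is not None and len(y) > n_predictors + 1:
        r2a = adjusted_r2(r2, len(y), n_predictors)
    flagged = flag_outliers(y, yhat, labels) if len(y) >= 3 else []
    return ValidationReport(
        label=label,
        m=len(y),
        r2=r2,
        r2_printed=r2p,
        r2_adj=r2a,
        rmse=rmse(y, yhat),
        outliers=flagged,
    )


@dataclass
class BaggingResult:
    """Out-of-bag validation of a bagged M5 ensemble."""

    n_models: int
    sample_fraction: float
    seed: int
    oob_predictions: np.ndarray  # one mean out-of-bag prediction per record
    oob_counts: np.ndarray  # number of models for which the record was held out
    q2: float
    rmse: float
    trees: list[ModelTree] = field(default_factory=list, repr=False)


def bagging_validate(
    X,
    y,
    n_models: int = 100,
    sample_fraction: float = 0.6,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
    whitelist=None,
    with_replacement: bool = False,
    smoothed: bool = True,
    max_redraws: int = 10,
) -> BaggingResult:
    """Fit ``n_models`` M5 trees on seeded draws and score out-of-bag Q^2.

    Draws are without replacement of ``ceil(sample_fraction * n)`` records
    (subsampling); ``with_replacement=True`` gives the classical same-size
    bootstrap.  Each record's out-of-bag prediction is the mean over models
    whose draw excluded it; Q^2 is the standard-variant R^2 of those
    predictions.  If any record is never out of bag, the whole draw set is
    redrawn with an incremented seed, at most ``max_redraws`` times.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    if isinstance(X, pd.DataFrame):
        frame = X
    else:
        frame = pd.DataFrame(np.asarray(X, dtype=float))
        frame.columns = [f"x{i}" for i in range(frame.shape[1])]
    y = np.asarray(y, dtype=float)
    n = len(frame)
    size = math.ceil(sample_fraction * n) if not with_replacement else n

    for attempt in range(max_redraws):
        rng = np.random.default_rng(seed + attempt)
        draws = []
        for _ in range(n_models):
            if with_replacement:
                draws.append(rng.integers(0, n, size=n))
            else:
                draws.append(rng.permutation(n)[:size])
        oob_sets = [np.setdiff1d(np.arange(n), draw) for draw in draws]
        covered = np.zeros(n, dtype=int)
        for oob in oob_sets:
            covered[oob] += 1
        if (covered > 0).all():
            break
    else:
        raise RuntimeError(
            f"some records were never out of bag after {max_redraws} redraws; "
            "decrease sample_fraction or increase n_models"
        )

    sums = np.zeros(n)
    trees = []
    for draw, oob in zip(draws, oob_sets):
        tree = fit_m5p(
            frame.iloc[draw], y[draw], hyperparams=hyperparams, whitelist=whitelist
        )
        trees.append(tree)
        if len(oob):
            sums[oob] += tree.predict(frame.iloc[oob], smoothed=smoothed)
    oob_pred = sums / covered
    return BaggingResult(
        n_models=n_models,
        sample_fraction=sample_fraction,
        seed=seed + attempt,
        oob_predictions=oob_pred,
        oob_counts=covered,
        q2=r_squared(y, oob_pred, variant="standard"),
        rmse=rmse(y, oob_pred),
        trees=trees,
    )
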
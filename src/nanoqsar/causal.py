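"""PC-algorithm causal discovery over descriptors and activity.

Constraint-based discovery for continuous, approximately linear-Gaussian
data: start from the complete undirected graph, delete edges whose
endpoints test conditionally independent (partial correlation with the
Fisher z test), record the separating sets, orient v-structures, and close
under the Meek rules.  The output is a CPDAG — the Markov-equivalence class
of DAGs consistent with the detected independences.

The skeleton phase is the order-independent ("stable") variant: adjacency
sets are frozen per conditioning-set size, so the result does not depend on
column order.

Small-sample honesty: the study's per-group sample sizes (3-8 records) are
far below any reliable regime for conditional-independence testing, so
:func:`run_causal_analysis` attaches an explicit warning to any analysis
with fewer than 15 rows instead of suppressing output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CITestResult",
    "CausalGraph",
    "partial_correlation",
    "fisher_z_test",
    "pc_skeleton",
    "orient_edges",
    "meek_closure",
    "run_causal_analysis",
]

SMALL_SAMPLE_WARNING_N = 15


@dataclass(frozen=True)
class CITestResult:
    """One conditional-independence test."""

    pair: tuple[str, str]
    conditioning: tuple[str, ...]
    partial_corr: float
    statistic: float
    p_value: float
    independent: bool
    alpha: float


@dataclass
class CausalGraph:
    """Partially directed graph (CPDAG) with separation sets.

    ``undirected`` holds unordered pairs; ``directed`` holds (tail, head)
    pairs.  ``sepsets`` maps each removed pair to the conditioning set that
    rendered it independent.
    """

    nodes: tuple[str, ...]
    undirected: set[frozenset] = field(default_factory=set)
    directed: set[tuple[str, str]] = field(default_factory=set)
    sepsets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    def has_edge(self, a: str, b: str) -> bool:
        return (
            frozenset((a, b)) in self.undirected
            or (a, b) in self.directed
            or (b, a) in self.directed
        )

    def neighbors(self, a: str) -> set[str]:
        out = set()
        for pair in self.undirected:
            if a in pair:
                out |= pair - {a}
        for tail, head in self.directed:
            if tail == a:
                out.add(head)
            elif head == a:
                out.add(tail)
        return out

    def edge_count(self) -> int:
        return len(self.undirected) + len(self.directed)

    def directed_part(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def validate(self) -> None:
        for pair in self.undirected:
            if len(pair) != 2:
                raise ValueError("self-edge in undirected part")
        if not nx.is_directed_acyclic_graph(self.directed_part()):
            raise ValueError("directed part contains a cycle")

    def edges_as_tuples(self) -> list[tuple[str, str, str]]:
        """Sorted edge list as (a, b, kind) with kind in {"--", "->"}."""
        out = [(min(p), max(p), "--") for p in self.undirected]
        out += [(t, h, "->") for t, h in self.directed]
        return sorted(out)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def partial_correlation(data, i, j, conditioning=()) -> float:
    """Partial correlation of columns ``i`` and ``j`` given ``conditioning``.

    Computed as the correlation of OLS residuals after regressing each
    variable on the conditioning set (with intercept); with an empty set it
    reduces to the Pearson correlation.

    Raises
    ------
    ValueError
        If n <= |S| + 2, a column is constant, or the conditioning design is
        singular (collinear), named in the message.
    """
    frame = _as_frame(data)
    conditioning = tuple(conditioning)
    n = len(frame)
    if n <= len(conditioning) + 2:
        raise ValueError("need n > |S| + 2 rows for a partial correlation")
    xi = frame[i].to_numpy(dtype=float)
    xj = frame[j].to_numpy(dtype=float)
    for name, col in ((i, xi), (j, xj)):
        if np.std(col) == 0:
            raise ValueError(f"column {name!r} is constant")
    if conditioning:
        Z = np.column_stack(
            [frame[list(conditioning)].to_numpy(dtype=float), np.ones(n)]
        )
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError(f"singular conditioning design for set {conditioning!r}")
        xi = xi - Z @ np.linalg.lstsq(Z, xi, rcond=None)[0]
        xj = xj - Z @ np.linalg.lstsq(Z, xj, rcond=None)[0]
        if np.std(xi) == 0 or np.std(xj) == 0:
            # residual is exactly explained by the conditioning set
            return 0.0
    r = float(np.corrcoef(xi, xj)[0, 1])
    return max(-1.0, min(1.0, r))


def fisher_z_test(pcor: float, n: int, s: int, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Fisher z test of zero partial correlation.

    Returns ``(statistic, p_value, independent)`` where the statistic is
    ``sqrt(n - s - 3) * |atanh(pcor)|`` and independence is declared when
    ``p > alpha``.

    Raises
    ------
    ValueError
        If ``n - s - 3 <= 0`` (sample too small for the conditioning size).
    """
    dof = n - s - 3
    if dof <= 0:
        raise ValueError(
            f"Fisher z test needs n - |S| - 3 > 0 (n={n}, |S|={s}); "
            "use a larger sample or a smaller conditioning set"
        )
    clipped = max(-1 + 1e-15, min(1 - 1e-15, pcor))
    z = 0.5 * math.log((1 + clipped) / (1 - clipped))
    statistic = math.sqrt(dof) * abs(z)
    p_value = 2.0 * (1.0 - stats.norm.cdf(statistic))
    return statistic, p_value, p_value > alpha


def pc_skeleton(
    data, alpha: float = 0.05, max_cond: int | None = None
) -> tuple[CausalGraph, list[CITestResult]]:
    """PC-stable skeleton search.

    For growing conditioning-set size ``l = 0, 1, 2, ...`` each remaining
    edge (i, j) is tested against all size-``l`` subsets of the frozen
    adjacency of ``i`` and of ``j``; on independence the edge is removed and
    the separating set recorded.  Returns the undirected graph with sepsets
    plus the full test log.
    """
    frame = _as_frame(data)
    names = tuple(str(c) for c in frame.columns)
    n = len(frame)
    if n < 10:
        raise ValueError("pc_skeleton needs at least 10 rows")
    if len(names) < 2:
        raise ValueError("pc_skeleton needs at least 2 variables")
    graph = CausalGraph(nodes=names)
    for a, b in combinations(names, 2):
        graph.undirected.add(frozenset((a, b)))
    log: list[CITestResult] = []
    level = 0
    while True:
        if max_cond is not None and level > max_cond:
            break
        # freeze adjacencies for order independence
        adjacency = {a: graph.neighbors(a) for a in names}
        if all(len(adjacency[a]) - 1 < level for a in names):
            break
        for a, b in combinations(names, 2):
            if not graph.has_edge(a, b):
                continue
            removed = False
            for base in (a, b):
                other = b if base == a else a
                candidates = sorted(adjacency[base] - {other})
                if len(candidates) < level:
                    continue
                for subset in combinations(candidates, level):
                    if n - level - 3 <= 0:
                        raise ValueError(
                            f"cannot test edge {a}-{b} at conditioning size {level}: "
                            f"sample size {n} too small"
                        )
                    try:
                        pcor = partial_correlation(frame, a, b, subset)
                    except ValueError as exc:
                        raise ValueError(f"edge {a}-{b} | {subset}: {exc}") from exc
                    statistic, p_value, independent = fisher_z_test(
                        pcor, n, level, alpha
                    )
                    log.append(
                        CITestResult(
                            pair=(a, b),
                            conditioning=subset,
                            partial_corr=pcor,
                            statistic=statistic,
                            p_value=p_value,
                            independent=independent,
                            alpha=alpha,
                        )
                    )
                    if independent:
                        graph.undirected.discard(frozenset((a, b)))
                        graph.sepsets[frozenset((a, b))] = subset
                        removed = True
                        break
                if removed:
                    break
        level += 1
    return graph, log


def orient_edges(skeleton: CausalGraph) -> CausalGraph:
    """Orient v-structures and close under the Meek rules; returns a CPDAG.

    For every nonadjacent pair (a, b) with common neighbour c not in
    sepset(a, b), orient a -> c <- b.  Conflicting orientations keep the
    first by deterministic (sorted) order, with a warning.
    """
    cpdag = CausalGraph(
        nodes=skeleton.nodes,
        undirected=set(skeleton.undirected),
        directed=set(skeleton.directed),
        sepsets=dict(skeleton.sepsets),
    )
    for a, b in combinations(sorted(cpdag.nodes), 2):
        if cpdag.has_edge(a, b):
            continue
        sepset = cpdag.sepsets.get(frozenset((a, b)), ())
        common = sorted(
            c
            for c in cpdag.nodes
            if c not in (a, b) and cpdag.has_edge(a, c) and cpdag.has_edge(b, c)
        )
        for c in common:
            if c in sepset:
                continue
            for tail in (a, b):
                pair = frozenset((tail, c))
                if pair in cpdag.undirected:
                    cpdag.undirected.discard(pair)
                    cpdag.directed.add((tail, c))
                elif (c, tail) in cpdag.directed:
                    warnings.warn(
                        f"conflicting v-structure orientation at {tail}->{c}; "
                        "keeping the earlier orientation"
                    )
    meek_closure(cpdag)
    cpdag.validate()
    return cpdag


def meek_closure(graph: CausalGraph) -> CausalGraph:
    """Apply Meek rules 1-4 until fixpoint (in place)."""

    def directed(a, b):
        return (a, b) in graph.directed

    def undirected(a, b):
        return frozenset((a, b)) in graph.undirected

    def orient(a, b):
        graph.undirected.discard(frozenset((a, b)))
        graph.directed.add((a, b))

    changed = True
    while changed:
        changed = False
        for pair in sorted(graph.undirected, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            for tail, head in ((a, b), (b, a)):
                # R1: c -> tail and c not adjacent to head  =>  tail -> head
                if any(
                    directed(c, tail) and not graph.has_edge(c, head)
                    for c in graph.nodes
                    if c not in (tail, head)
                ):
                    orient(tail, head)
                    changed = True
                    break
                # R2: tail -> c -> head  =>  tail -> head
                if any(
                    directed(tail, c) and directed(c, head)
                    for c in graph.nodes
                    if c not in (tail, head)
                ):
                    orient(tail, head)
                    changed = True
                    break
                # R3: tail - c -> head and tail - d -> head, c,d nonadjacent
                mids = [
                    c
                    for c in graph.nodes
                    if c not in (tail, head)
                    and undirected(tail, c)
                    and directed(c, head)
                ]
                if any(
                    not graph.has_edge(c, d)
                    for c, d in combinations(mids, 2)
                ):
                    orient(tail, head)
                    changed = True
                    break
                # R4: tail - c, c -> d, d -> head, c adjacent to head
                if any(
                    undirected(tail, c)
                    and directed(c, d)
                    and directed(d, head)
                    and graph.has_edge(tail, d)
                    for c in graph.nodes
                    for d in graph.nodes
                    if len({tail, head, c, d}) == 4
                ):
                    orient(tail, head)
                    changed = True
                    break
            if changed:
                break
    return graph


@dataclass
class GroupCausalResult:
    """PC output for one record group (or the pooled data)."""

    label: str
    n: int
    graph: CausalGraph | None
    tests: list[CITestResult]
    note: str | None = None


def run_causal_analysis(
    data,
    groups: dict[str, list] | None = None,
    alpha: float = 0.05,
    variables=None,
) -> dict[str, GroupCausalResult]:
    """Run skeleton + orientation on the pooled data and on each group.

    ``data`` is a DataFrame whose columns include the analysis variables
    (default: all columns).  ``groups`` maps a label to a list of row
    indices/labels.  Groups too small to test (n < 10 or n <= |S|+3 for the
    required tests) are reported as ``note="insufficient n"`` rather than
    raising; analyses with n < 15 carry a reliability warning in ``note``.
    """
    frame = _as_frame(data)
    if variables is not None:
        frame = frame[list(variables)]
    results: dict[str, GroupCausalResult] = {}

    def analyse(label: str, sub: pd.DataFrame) -> GroupCausalResult:
        n = len(sub)
        if n < 10 or n - 3 <= 0:
            return GroupCausalResult(label=label, n=n, graph=None, tests=[], note="insufficient n")
        note = None
        if n < SMALL_SAMPLE_WARNING_N:
            note = (
                f"n={n} is far below a reliable regime for conditional-"
                "independence testing; interpret edges qualitatively only"
            )
            warnings.warn(f"{label}: {note}")
        try:
            skeleton, log = pc_skeleton(sub, alpha=alpha, max_cond=max(0, n - 4))
        except ValueError as exc:
            return GroupCausalResult(label=label, n=n, graph=None, tests=[], note=str(exc))
        cpdag = orient_edges(skeleton)
        return GroupCausalResult(label=label, n=n, graph=cpdag, tests=log, note=note)

    results["pooled"] = analyse("pooled", frame)
    for label, rows in (groups or {}).items():
        sub = frame.loc[rows] if set(rows) <= set(frame.index) else frame.iloc[list(rows)]
        results[label] = analyse(str(label), sub)
    return results
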
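"""Seedable synthetic-data generators for estimator recovery tests.

Three generators mirror the statistical structure the analysis assumes:

* :func:`gen_piecewise` — feature tables with a piecewise-linear response
  plus additive Gaussian noise, for model-tree breakpoint/slope recovery;
* :func:`gen_dag` — linear-Gaussian structural-equation data on a known
  DAG, for causal-discovery recovery (the true CPDAG is returned alongside);
* :func:`gen_np_like` — nanoparticle-like records whose measured properties
  span the study table's observed ranges (hydrodynamic size 240-840 nm,
  density 2.6-9.7 g/cm^3) and whose activity follows a configurable ground
  truth (default: piecewise in the Wigner-Seitz radius with a linear
  hydrodynamic-size term in the high-r_wz branch, emulating the fitted
  tree's structure), for end-to-end pipeline tests.

Every generator is a pure function of its spec: random streams are derived
from ``(seed, generator-id)`` through :func:`numpy.random.SeedSequence`, so
adding a generator never perturbs the streams of existing ones.  Ground
truth is always returned with the data so recovery tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from nanoqsar.causal import CausalGraph, meek_closure
from nanoqsar.dataset_io import Dataset, NPRecord, load_atomic_masses, load_ion_table, molecular_weight
from nanoqsar.descriptors import covalent_index, wigner_seitz_radius

__all__ = [
    "PiecewiseSpec",
    "DagSpec",
    "gen_piecewise",
    "gen_dag",
    "gen_np_like",
    "true_cpdag",
]

# stable per-generator stream keys (never renumber; append only)
_STREAM_IDS = {"piecewise": 1, "dag": 2, "np_like": 3}


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_IDS[generator]]))


@dataclass(frozen=True)
class PiecewiseSpec:
    """Piecewise-linear response on one named split attribute.

    ``segment_models`` holds, per segment (in breakpoint order), a mapping
    attribute -> slope plus an ``"intercept"`` entry.  Attributes are drawn
    uniformly on ``ranges``.
    """

    n: int
    attributes: tuple[str, ...]
    split_attribute: str
    breakpoints: tuple[float, ...]
    segment_models: tuple[dict, ...]
    noise_sd: float
    seed: int
    ranges: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.split_attribute not in self.attributes:
            raise ValueError("split_attribute must be one of attributes")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.segment_models) != len(self.breakpoints) + 1:
            raise ValueError("need one segment model per interval")
        if self.n < 10 * len(self.segment_models):
            raise ValueError("n must be >= 10 per segment")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_piecewise(spec: PiecewiseSpec) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Generate (features, targets, truth) for a piecewise-linear response."""
    spec.validate()
    rng = _rng(spec.seed, "piecewise")
    columns = {}
    for name in spec.attributes:
        lo, hi = spec.ranges.get(name, (0.0, 1.0))
        columns[name] = rng.uniform(lo, hi, size=spec.n)
    X = pd.DataFrame(columns)
    split_vals = X[spec.split_attribute].to_numpy()
    segment = np.searchsorted(np.asarray(spec.breakpoints), split_vals, side="right")
    y = np.empty(spec.n)
    for s, model in enumerate(spec.segment_models):
        mask = segment == s
        vals = np.full(mask.sum(), float(model.get("intercept", 0.0)))
        for name in spec.attributes:
            if name in model:
                vals += model[name] * X.loc[mask, name].to_numpy()
        y[mask] = vals
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    truth = {
        "split_attribute": spec.split_attribute,
        "breakpoints": tuple(spec.breakpoints),
        "segment_models": tuple(dict(m) for m in spec.segment_models),
        "noise_sd": spec.noise_sd,
    }
    return X, y, truth


@dataclass(frozen=True)
class DagSpec:
    """Linear-Gaussian structural-equation model on a known DAG.

    ``edges`` maps (parent, child) to a weight; ``noise_sd`` maps node to
    its Gaussian noise sd (default 1.0).
    """

    nodes: tuple[str, ...]
    edges: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    n: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for (parent, child) in self.edges:
            if parent not in self.nodes or child not in self.nodes:
                raise ValueError(f"edge ({parent}, {child}) names an unknown node")
        for node, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd for {node!r} must be > 0")
        order = self.topological_order()
        if order is None:
            raise ValueError("adjacency is cyclic")

    def topological_order(self) -> list[str] | None:
        children = {a: set() for a in self.nodes}
        indegree = {a: 0 for a in self.nodes}
        for parent, child in self.edges:
            children[parent].add(child)
            indegree[child] += 1
        frontier = sorted(a for a in self.nodes if indegree[a] == 0)
        order = []
        while frontier:
            node = frontier.pop(0)
            order.append(node)
            for child in sorted(children[node]):
                indegree[child] -= 1
                if indegree[child] == 0:
                    frontier.append(child)
            frontier.sort()
        return order if len(order) == len(self.nodes) else None


def gen_dag(spec: DagSpec) -> tuple[pd.DataFrame, CausalGraph]:
    """Simulate the SEM in topological order; also return the true CPDAG."""
    spec.validate()
    rng = _rng(spec.seed, "dag")
    data = {}
    for node in spec.topological_order():
        sd = float(spec.noise_sd.get(node, 1.0))
        value = rng.normal(0.0, sd, size=spec.n)
        for (parent, child), weight in spec.edges.items():
            if child == node:
                value = value + weight * data[parent]
        data[node] = value
    frame = pd.DataFrame({node: data[node] for node in spec.nodes})
    return frame, true_cpdag(spec)


def true_cpdag(spec: DagSpec) -> CausalGraph:
    """Markov-equivalence class (CPDAG) of the spec's DAG.

    Skeleton plus v-structure arrowheads, closed under the Meek rules.
    """
    adjacent = {frozenset((a, b)) for a, b in spec.edges}
    parents: dict[str, set[str]] = {node: set() for node in spec.nodes}
    for parent, child in spec.edges:
        parents[child].add(parent)
    graph = CausalGraph(nodes=tuple(spec.nodes), undirected=set(adjacent))
    for child in spec.nodes:
        for a, b in combinations(sorted(parents[child]), 2):
            if frozenset((a, b)) not in adjacent:
                for tail in (a, b):
                    graph.undirected.discard(frozenset((tail, child)))
                    graph.directed.add((tail, child))
    meek_closure(graph)
    graph.validate()
    return graph


# oxide catalogue for nanoparticle-like sampling (formula only; masses and
# ion properties come from the bundled reference tables)
_OXIDE_CATALOGUE = (
    "Al2O3", "CeO2", "Co3O4", "CoO", "Cr2O3", "CuO", "Fe2O3", "Fe3O4",
    "Gd2O3", "HfO2", "In2O3", "La2O3", "Mn2O3", "Ni2O3", "NiO", "Sb2O3",
    "SiO2", "SnO2", "TiO2", "WO3", "Y2O3", "Yb2O3", "ZnO", "ZrO2",
)

HYDRO_RANGE = (240.0, 840.0)  # nm, spanning the study table
DENSITY_RANGE = (2.6, 9.7)  # g/cm^3, spanning the study table
RWZ_BREAK = 0.196  # ground-truth branch point, the study's printed boundary


def _default_activity_rule(hydro: float, density: float, rwz: float, ci: float) -> float:
    """Piecewise ground truth emulating the fitted tree's structure.

    High-r_wz branch: activity declines linearly in hydrodynamic size
    (aggregation-dominated, weakly inhibiting).  Low-r_wz branch: activity
    rises with r_wz from a strongly inhibited baseline (dissolution-
    dominated).  Values stay within the study's observed activity range.
    """
    if rwz > RWZ_BREAK:
        return 1.22 - 0.0005 * (hydro - HYDRO_RANGE[0])
    return 0.62 + 3.0 * (rwz - 0.13)


def gen_np_like(
    n: int,
    seed: int,
    noise_sd: float = 0.02,
    activity_rule=None,
) -> tuple[Dataset, dict]:
    """Generate nanoparticle-like records with descriptor-consistent columns.

    Formulas are sampled from a built-in oxide catalogue; hydrodynamic size
    and density are uniform over the study ranges; r_wz and CI are computed
    through the descriptors module (so synthetic descriptor columns can
    never drift from the computation); activity follows ``activity_rule``
    (default :func:`_default_activity_rule`) plus Gaussian noise, floored at
    zero.  Records carry unique ids (``formula#k``) because formulas repeat
    for n beyond the catalogue size.

    Returns the dataset and a truth record (rule parameters and noise sd).
    """
    if n < 5:
        raise ValueError("n must be >= 5")
    rule = activity_rule or _default_activity_rule
    rng = _rng(seed, "np_like")
    masses = load_atomic_masses("builtin")
    ions = load_ion_table("builtin")
    records = []
    formulas = rng.choice(len(_OXIDE_CATALOGUE), size=n)
    hydro = rng.uniform(*HYDRO_RANGE, size=n)
    density = rng.uniform(*DENSITY_RANGE, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for k in range(n):
        formula = _OXIDE_CATALOGUE[formulas[k]]
        mw = molecular_weight(formula, masses)
        rwz = wigner_seitz_radius(mw, density[k])
        ion = ions[formula]
        ci = covalent_index(ion.electronegativity, ion.ionic_radius)
        activity = max(0.0, rule(hydro[k], density[k], rwz, ci) + noise[k])
        records.append(
            NPRecord(
                formula=formula,
                hydro_size=float(hydro[k]),
                density=float(density[k]),
                activity=float(activity),
                subset="train",
                rwz=rwz,
                ci=ci,
                record_id=f"{formula}#{k}",
            )
        )
    truth = {
        "rule": "default_piecewise" if activity_rule is None else "custom",
        "rwz_break": RWZ_BREAK,
        "noise_sd": noise_sd,
    }
    return Dataset(records), truth
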
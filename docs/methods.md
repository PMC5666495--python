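# Methods

This note records the models implemented by `nanoqsar`, the numerical
conventions that affect results, the design choices made where the
published description is silent or self-inconsistent, and what the test
suite does and does not establish.

## Data

The study table covers 24 silica- and metal-oxide nanoparticles with
hydrodynamic size ∅_hyd (nm, measured in Holtfreter's medium), bulk mass
density ρ (g/cm³), two theoretical descriptors (below), and residual ZHE1
enzymatic activity A (mmol/mg·min); the nanoparticle-free control assay
reads 1.25. Five oxides (CeO₂, NiO, Sb₂O₃, Yb₂O₃, ZrO₂) are marked as the
external validation set; the remaining 19 are the training set. The table
ships as packaged CSV and is treated as canonical, including one cell that
disagrees with its own generating formula (below).

## Descriptors

**Wigner–Seitz radius.** r_wz = (3M / 4πρ)^(1/3) with M in g/mol from
IUPAC 2021 standard atomic weights (bundled, 4 decimals) and ρ in g/cm³.
The study table prints r_wz in an undefined "a.u." scale; reverse
evaluation shows the printed column equals the raw value divided by 10.
That factor is implemented as the named constant `RWZ_TABLE_SCALE = 0.1`
and not interpreted physically. Under this convention 23 of 24 printed
values agree to ±0.003; CoO prints 0.144 where the formula gives 0.141.
The fixture keeps the printed value, `compute_descriptor_table` flags the
row, and exact-reproduction checks exclude CoO. Whether the printed CoO
value used a different density or molar mass is not determinable.

**Covalent index.** CI = χ²·r with χ the cation's Pauling
electronegativity and r its ionic radius in pm (pm makes the printed
magnitudes come out without any extra factor). The source does not print
its χ/r values, so the bundled ion table stores standard Pauling χ per
cation and back-computes r = CI/χ² from the printed CI column (to 4
decimals, so CI reproduces exactly). The back-computed radii all land
within 0.01 pm of physically sensible round values (Zn²⁺ 74 pm, Ni²⁺ 69,
Cu²⁺ 73, Si⁴⁺ 40, La³⁺ 103.2), which corroborates the χ assignment. The
table is keyed by oxide formula rather than bare cation so mixed-valence
oxides (Fe₃O₄, Co₃O₄) carry one effective pair.

## M5 model tree

Growth maximizes the standard-deviation reduction
SDR = sd(T) − Σᵢ |Tᵢ|/|T|·sd(Tᵢ) over all attributes and midpoint
thresholds between adjacent observed values. Conventions, each of which
moves thresholds and is therefore fixed and tested:

* sample (n−1) standard deviation; singleton children contribute sd 0;
* both children of an admissible split must hold at least `min_instances`
  rows (the leaf minimum);
* growth stops when n < 2·`min_instances` or node sd < `sd_fraction` of
  the root sd;
* SDR ties break toward the earlier column, then the smaller threshold.

Node models are OLS (numpy least squares) over the attributes occurring in
splits of the node's subtree, optionally extended by a caller-supplied
whitelist; zero-variance and collinear columns are dropped
deterministically (first-listed kept), then terms are removed greedily
while the adjusted error err·(n+v)/(n−v) decreases (err = mean absolute
residual, v = parameter count including intercept).

Pruning compares, bottom-up, the node model against its subtree on the
node's own rows, both scored by rmse·(n + 2v)/(n − v). For the subtree, v
aggregates every leaf model's parameters plus one per split threshold.
The multiplier 2 follows the classic M5 software lineage; without it, the
in-sample gain of an SDR-optimal split on pure noise beats the penalty and
noise trees survive pruning (measured: 0/50 noise collapses at multiplier
1 with per-leaf scoring vs 47/50 with this rule, while noiseless piecewise
structure is preserved in 25/25 runs). A node model that is exact up to
float noise always wins the tie, so perfectly linear data collapse to a
single linear leaf. Smoothed prediction blends the leaf value along the
root path as p′ = (n·p + k·q)/(n + k), n being the rows of the node below
and q the current node's model value.

Hyperparameter defaults are the canonical M5/M5P settings —
`min_instances = 4`, `sd_fraction = 0.05`, `smoothing_k = 15` — since the
study names the algorithm but no settings.

**Relative importance.** The published RI procedure ("mean deviation of
correct classifications") is not operational for a regression tree, so RI
is defined here as each attribute's share of n-weighted SDR over the
splits made on it, normalized to 100 %. Attributes absent from every split
but present in leaf models receive a share proportional to their
n-weighted standardized leaf coefficients, scaled into the split total; a
single-leaf intercept-only tree yields a uniform RI with a warning. For a
bagged ensemble, per-tree RI vectors are averaged. Only the rank order is
asserted anywhere; the published percentages are not reproducible from any
SDR-based definition we could construct.

## Validation

Two R² variants are kept because the study prints the explained-to-total
sum-of-squares ratio Σ(ŷ−ȳ)²/Σ(y−ȳ)² rather than the standard
1 − Σ(y−ŷ)²/Σ(y−ȳ)²; both agree for an in-sample OLS fit with intercept,
and the standard variant is used for out-of-bag and external predictions
(the printed form can exceed 1 there). RMSE uses the study's m−1
denominator. Adjusted R² is 1 − (1−R²)(n−1)/(n−p−1).

Bagging draws `ceil(0.6·n)` records without replacement per model
(matching the stated "covers ~60 % of the training set" coverage reading;
classical same-size with-replacement bootstrap is available via a flag),
fits one tree per draw (default 100, seedable), and scores each record by
the mean prediction of the models that excluded it; Q² is the standard R²
of those out-of-bag means. If any record is never out of bag the draw set
is redrawn with an incremented seed (at most 10 times, then an error).

Outliers are records whose |residual| exceeds three sample standard
deviations of all residuals, candidate included; identical residuals flag
nothing.

The activity-ranging splitter sorts records by activity, sends every
stride-th record to the test side, then deterministically rebalances so
each multi-member stoichiometry class (MeO, Me₂O₃, MeO₂ from the parsed
cation:O ratio; others pooled) appears in both subsets while the stride
count is preserved. It is provided for completeness; the canonical split
is the explicit subset marking in the fixture.

## PC causal discovery

Conditional independence is tested by Fisher-z on partial correlations
(OLS-residual correlation; the study names a likelihood criterion but no
test, and Fisher-z is the standard exactly computable choice for
continuous data): statistic √(n−|S|−3)·|atanh(ρ̂)|, two-sided normal
p-value, independence declared at p > α (default α = 0.05). The skeleton
phase is PC-stable (adjacency sets frozen per level), making the output
independent of column order; sepsets are recorded per removed edge.
Orientation finds v-structures a→c←b for nonadjacent a, b with common
neighbour c ∉ sepset(a,b) (conflicts keep the first orientation by sorted
order, with a warning) and closes under Meek rules 1–4; the directed part
is verified acyclic.

The study's per-group sample sizes (3–8 records) are far below any regime
in which these tests are reliable. `run_causal_analysis` computes them
anyway but attaches an explicit warning below n = 15 and reports groups
too small to test as "insufficient n" rather than raising.

## Synthetic generators

All generators derive their stream from (seed, generator-id) via
`numpy.random.SeedSequence`, so outputs are pure functions of the spec and
adding a generator never perturbs existing streams. Ground truth is
returned with the data.

* `gen_piecewise`: uniform features, piecewise-linear response on one
  split attribute, additive Gaussian noise.
* `gen_dag`: linear-Gaussian structural equations simulated in topological
  order; the true CPDAG (skeleton + v-structures + Meek closure) is
  returned for comparison.
* `gen_np_like`: formulas drawn from a 24-oxide catalogue; ∅_hyd uniform
  on 240–840 nm and ρ on 2.6–9.7 g/cm³ (the study table's observed
  ranges); r_wz and CI recomputed through the descriptors module so
  synthetic descriptor columns can never drift; activity defaults to a
  piecewise rule emulating the fitted tree — a linearly size-declining
  branch above r_wz = 0.196 and an r_wz-increasing, strongly inhibited
  branch below — plus Gaussian noise (default sd 0.02), keeping values
  inside the study's 0.62–1.25 activity range.

What these generators deliberately do not model: real dissolution
chemistry, dose–response, measurement error structure of dynamic light
scattering, or correlations between formula and size. Recovery tests on
them establish estimator correctness under the model's own assumptions,
not performance on real laboratory data.

## Reproduction status and known limitations

The descriptor layer and the subset correlation reproduce the published
table exactly under the conventions above (23/24 and 24/24 cells; the
eight large-r_wz training oxides give size–activity r = −0.91). The
model-fit layer does not reproduce the published statistics, and the
package reports this rather than hiding it:

* The SDR criterion selects the first split on r_wz — agreeing with the
  published tree — but at threshold 0.1925 (between Cr₂O₃'s 0.191 and
  Fe₂O₃'s 0.194), one position below the published 0.196 boundary. The
  choice is robust to the sd denominator and the per-side minimum. Note
  the published groups are themselves not consistent with a 0.196
  boundary (WO₃ at 0.197 is listed in the low branch's group).
* The published node groups (sizes 8/6/3/2, separating CoO and SnO₂ from
  Cr₂O₃/ZnO/CuO) are not producible by any axis-aligned tree on the four
  printed descriptors: no single-attribute threshold separates those
  oxides, and 2-record leaves violate the minimum leaf size. Consequently
  the published training fit (adjusted R² 0.85, RMSE 0.062) — which
  implies near-constant leaves over exactly those groups — is out of
  reach: the canonical pipeline measures adjusted R² 0.61 unsmoothed
  before pruning and a single-leaf model after pruning. With 19 records
  and k = 15, smoothing leaves the leaf model ~9 % weight on a depth-2
  path, so smoothed training predictions collapse toward the mean.
* Out-of-bag Q² on the 19-record fixture is negative for every seed and
  configuration tried (≈ −0.2 to −1.0), because the strongly inhibited
  oxides cannot be isolated by splits and are therefore always
  mispredicted when held out. The same bagging code reaches Q² = 1.0 on
  noiseless linear data and 0.97 on piecewise data, so this is a property
  of the data, not the estimator. The two published bagging/external
  figures (0.69/0.80 in one place, 0.90/0.93 in another) disagree with
  each other as printed and neither is recoverable as an out-of-bag or
  external R² here; the reproduce report prints both comparisons without
  adjudicating.
* Cr₂O₃ is not a three-sigma outlier of any model this package fits; a
  model that groups Cr₂O₃ with ZnO and CuO (as the published tree does)
  predicts its activity well, which makes the published outlier claim
  internally inconsistent with the published grouping.
* The pooled descriptor–activity PC analysis removes the
  ∅_hyd–activity edge at α = 0.05 (marginal r = 0.166, p = 0.44, n = 24);
  the published qualitative cause–effect claim is not supported by the
  printed data under a Fisher-z PC run at that level.
* The polynomial CI–activity analysis for three oxides is not asserted
  anywhere: three points saturate any quadratic (R² = 1 by construction),
  so the published R² = 0.85 has no well-defined reconstruction;
  `poly_r2` warns on saturated fits.

The reproduce pipeline therefore reports split structure (first split,
depth-1 occupancy, node co-occurrence of ZnO/CuO/Cr₂O₃) from the grown
tree — the analogue of the published tree diagram — and fit statistics
from the pruned, smoothed predictive model, with the canonical
19/5 split, printed descriptor columns (recomputation behind a flag), an
all-attribute leaf-model whitelist (the study describes a multivariate
linear model at each node), 100 bagged models at 60 % subsampling, and
α = 0.05.

Problem sizes used by the test suite were chosen to exercise each
estimator at scales where its asymptotics visibly hold: n = 200 for
piecewise recovery, n = 100 × 50 seeds for noise pruning, n = 5000 × 40
seeds at α = 0.01 for CPDAG recovery on faithful unit-weight structures
(chains, collider, diamond — structures with near-cancelling signed paths
violate faithfulness and are outside PC's correctness guarantee), and the
19-record fixture for every study-data statistic.
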
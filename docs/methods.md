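# Methods

## Model and procedure

The package operates on a labeled score set: per-sample positive-class
probabilities `p ∈ [0, 1]` with binary ground truth. An abstention interval
`[L, U]` is parameterized by an anchor `a` (offset of its center from the 0.5
decision threshold) and a half-width `w ≥ 0`:

    L = 0.5 + a − w,    U = 0.5 + a + w.

Prediction is trichotomous: positive if `p ≥ U`, negative if `p ≤ L`,
rejected otherwise. Two conventions are fixed here and used everywhere:

- **Boundary equality classifies.** Scores exactly on a bound receive a
  label rather than being rejected; with `w = 0` the rule degenerates to the
  plain threshold rule `p ≥ 0.5 + a → positive`, so the zero-width grid cell
  reproduces the no-abstention classifier exactly and has coverage 1.
- **Degenerate MCC is 0.** When any of the four denominator factors of the
  MCC vanishes (an empty predicted or actual class among the classified
  samples, including total abstention), the MCC — and hence the objective —
  is defined as 0. This keeps the grid objective well defined at every cell.

The optimizers evaluate `MCC × size_fraction` on a finite grid and return the
argmax together with the full grid and the Pareto front in
(MCC, size_fraction). A point is on the front iff no other evaluated point is
at least as good in both coordinates and strictly better in one; the product
argmax is therefore never strictly dominated by a front member.

An alternative reading of the procedure centers the abstention test on the
*maximum* class probability instead of the positive-class probability. The
two coincide for symmetric intervals but disagree for scores below 0.5 under
a nonzero anchor; this package takes the closed-form `L/U` definition above
as normative, since it is self-consistent and reproduces the published
reference intervals, and does not implement the max-probability variant.

## Grid parameters

| parameter | default | meaning |
|---|---|---|
| `interval_low` / `interval_high` / `interval_step` | 0 / 0.16 / 0.01 | half-widths form the half-open sequence `[low, high)`, i.e. 0.00–0.15: up to 30% of the probability range abstained |
| `anchor_width` | 0.2 | anchors span `[−0.2, +0.2]` — the interval center may shift up to 0.2 from the threshold |
| `num_anchors` | 20 | evenly spaced anchors including both endpoints; 20 points give a spacing of 0.4/19 ≈ 0.021 |
| `include_zero_anchor` | true | an even endpoint-inclusive grid excludes 0; injecting it guarantees the symmetric grid is a subset of the asymmetric one, so the asymmetric optimum can never be worse. `GridSpec.replication_profile()` disables the injection to keep the bare 20-point grid |

All units are probabilities. Ties in the argmax are broken deterministically:
smallest half-width first (least abstention), then the anchor nearest zero
(most symmetric), then the lower anchor. Intervals whose raw bounds leave
[0, 1] are clipped with a warning; the default grids never clip
(max `|a| + w` = 0.35).

Half-width grids are generated as `low + step·k` with the count computed once
from `(high − low)/step` under a 1e-9 slack, so float noise in the division
cannot add or drop a grid point.

## Synthetic data

`simulate_scores` draws labels Bernoulli(`positive_fraction`) and scores from
class-conditional Beta distributions — controls Beta(2, 8) (mean 0.2) and
cases Beta(8, 2) (mean 0.8) by default, at 10% prevalence. Beta laws are the
natural score model here: supported on [0, 1], arbitrarily skewed, and with a
closed-form CDF that yields an exact population oracle.
`population_objective` computes the expected objective of any interval from
Beta tail integrals (TP = π(1 − F₊(U)), FN = πF₊(L), FP = (1−π)(1 − F₋(U)),
TN = (1−π)F₋(L)), with the same degenerate-MCC convention as the sample
metric; the parameter-recovery tests check that the optimizer on 10,000
simulated scores lands within one grid-step objective gap of the population
optimum of the grid.

What the generator emulates: two overlapping unimodal score distributions
with controllable imbalance — the regime in which an asymmetric interval
helps. What it does not emulate: multimodal or poorly calibrated classifier
outputs, point masses at 0/1, label noise, or feature-level structure.
Passing tests on this generator therefore demonstrate correctness of the
optimization machinery and its statistical consistency under the stated
mixture, not performance guarantees on any particular clinical dataset.

`simulate_features` provides a minimal feature-space counterpart (two
isotropic Gaussian clouds a configurable separation apart) for exercising the
train/score pipeline; `downsample_balanced` retains the full minority class
and a seeded uniform without-replacement subsample of the majority class.
All generators draw from named sub-streams of a single integer seed and are
bit-reproducible.

## Experiment pipeline

`run_experiment` mirrors the standard evaluation shape: optional balancing
down-sample (applied to the whole dataset before splitting), a seeded
stratified hold-out split (per-class proportions preserved to within one
sample), a pluggable probabilistic base classifier — logistic regression by
default, behind a `fit`/`predict_proba` contract whose outputs are checked to
be probability rows summing to 1 — and a three-row report: none / symmetric /
asymmetric, each with MCC, rejected fraction, and the fitted interval.

By default the interval is selected on the same test scores it is reported
on, matching the published procedure. This tunes two parameters on the test
set and biases the reported MCC upward; `three_way=True` selects the interval
on a separate stratified half of the evaluation scores and reports on the
held-out half. Rejected fractions are reported exactly; display rounding
(3 decimals, percentages) happens only in the human-readable table.

## Numerical and design notes

- The sample-size choices in the test suite (n = 120–2,000 for property and
  behavioral checks, n = 10,000 for parameter recovery, 20 cells per grid
  axis) are the package's own: large enough that the Beta-mixture asymptotics
  visibly bind, small enough to keep the full suite in tens of seconds.
- Optimization is exhaustive over the grid, hence deterministic: identical
  inputs and grid yield bit-identical results. No continuous refinement of
  (anchor, half-width) is attempted; the grid resolution bounds the
  achievable precision of the selected interval (0.01 in half-width, ≈0.021
  in anchor by default).
- The zero-denominator MCC convention means a grid cell that empties a
  predicted class scores 0 rather than being excluded; such cells can never
  win the argmax against any cell with positive objective.
- CSV output uses 17-significant-digit floats and CSV input uses round-trip
  float parsing, so write-then-read of scores and grids is lossless.

## Limitations

- Binary classification only; no multi-class reject option.
- Scores are taken at face value: no probability calibration is performed,
  and a systematically miscalibrated classifier shifts the optimal anchor.
- No cost model for rejection: the product objective weights MCC and coverage
  implicitly, not via an explicit per-rejection cost.
- Selection on the evaluation scores (the default, for fidelity to the
  published procedure) optimistically biases the reported MCC; use the
  three-way split for honest estimates on new data.
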
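# Methods

## Model and procedure

Network inference is cast as p independent feature-ranking regressions: for
each target gene *j* the expression profile `x_j` (length N) is regressed on
the profiles of the candidate regulators, and the importance of each
regulator in that model becomes the weight of the corresponding directed
link. The regressors are randomized ensembles of fully grown regression
trees:

- **Random Forests (RF)** — each tree is grown on an N-draw bootstrap of the
  learning sample; at each node K candidate variables are drawn uniformly
  without replacement and for each the best threshold is found exhaustively
  among the midpoints of consecutive distinct sorted values.
- **Extra-Trees (ET)** — each tree is grown on the full sample; at each node
  K distinct variables are drawn and each receives a single threshold drawn
  uniformly within its observed range at that node; the best of the K random
  splits is kept. A node where all K drawn variables are locally constant
  becomes a leaf.

A split's quality is the total output-variance reduction
`#S·Var(S) − #S_t·Var(S_t) − #S_f·Var(S_f)`. A variable's importance in a
tree is the sum of this quantity over its split nodes; the ensemble
importance is the mean over trees.

**Variance convention.** All variances are *population* variances (divide by
the count). With this convention, and trees grown to purity, the summed
importances of a tree telescope exactly to `#S·Var(S)` of its root sample —
the test suite asserts this identity to 1e-8 relative on random trees. This
exact budget is also the reason gene profiles are normalized to unit
variance before fitting: every per-target model then distributes the same
total importance, making weights comparable across targets without any
per-model renormalization (importance renormalization by generalization
quality is deliberately not provided).

**Normalization** also centers each gene to mean zero, although tree splits
are threshold-based and means are irrelevant to them: centering makes the
synthetic-data checks and the normalization-idempotence property exact.
Constant genes map to all-zero columns instead of raising — flat probes
occur in real compendia — and a constant *target* receives an all-zero
weight vector without fitting a model.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `method` | `"RF"` | RF or ET randomization (see above) |
| `n_trees` (T) | 1000 | ensemble size per target gene |
| `k` (K) | `"sqrt"` | candidates per node; `"sqrt"` → `max(1, floor(sqrt(m)))`, `"all"` → m |
| `bootstrap` | True | RF only; `False` with `k="all"` is deterministic CART bagging input |
| `min_split` | 2 | minimum node size to attempt a split (trees fully grown, no pruning) |
| `regulators` | all genes | candidate regulator list (e.g. known transcription factors); non-candidates still appear as targets |

`RF` with `k="sqrt"` is the classic forest setting; `k="all"` (bagging)
performed best on dense in-silico multifactorial benchmarks, while `"sqrt"`
is preferable when the candidate-regulator set is large. K's `sqrt`
resolution uses `floor` and ties between equal-score splits break toward the
lowest variable index, then the lowest threshold — conventions chosen for
determinism, not dictated by the method.

## Numerical choices

- Variance reductions are computed from prefix sums in the algebraically
  equivalent form `(ΣL)²/nL + (ΣR)²/nR − (Σ)²/n`, clamped at zero against
  rounding.
- Split-selection ties are resolved within a relative tolerance band of
  1e-9: two splits whose scores differ only through floating-point summation
  order (e.g. two variables inducing the same partition) always resolve to
  the same choice. This keeps fitted trees invariant to row permutations and
  to exactly-representable affine rescalings of the raw inputs.
- Each ensemble consumes one seeded random stream split per tree via
  `SeedSequence.spawn`; per-target ensembles use independent substreams of
  the master seed, so results are independent of evaluation order and the
  p fits could be parallelized without changing output.
- ET thresholds are drawn as `lo + u·(hi − lo)` with `u ∈ [0, 1)`, so both
  children are always non-empty for a locally non-constant variable.

## Evaluation toolbox

Rankings are assessed against a gold standard of directed edges; the
negative universe is every ordered candidate pair that is not a positive
(or the explicitly 0-labelled pairs of a gold-standard file). Pairs missing
from a submitted ranking are appended with weight 0 in deterministic order —
submitted rankings may be partial.

- **AUPR** is computed as average precision (mean of precision at each
  positive's rank in the tie-broken total order); PR-space interpolation is
  avoided because it overestimates the area. Note the null mean of average
  precision sits slightly *above* the positive fraction for small positive
  counts (≈0.14 for 10 positives in 100 pairs).
- **AUROC** is the normalized Mann–Whitney concordance computed from weight
  ranks; exactly tied weights contribute 1/2 regardless of tie-break order.
- **Empirical p-values** are Monte-Carlo with the add-one estimator
  `(r+1)/(B+1)` under random edge orderings, so they saturate at `1/(B+1)`.
  The minute p-values quoted for the original challenge (down to 1e-54) came
  from the organizers' analytic extreme-value nulls and are not reproducible
  by permutation; a very good ranking here simply reports the floor.
- **Overall score** `−0.5·log10(gm_AUPR·gm_AUROC)` combines geometric means
  of per-network p-values (computed in log space). The formula reproduces
  the published challenge scores 37.428 and 28.165 from the published
  per-network p-values.
- **Directionality**: the asymmetry of a thresholded network (fraction of
  edges whose reverse is absent), and a direction error rate — asymmetric
  gold edges are ordered by `max(w_ij, w_ji)` (confidence that some link
  exists for the pair), the top `recall` fraction kept, and an edge counts
  as an error when `w_ji ≥ w_ij` (weight ties are errors). The conditioning
  of the error rate on recall admits several readings; this ordering-by-max
  interpretation is recorded in the command output.
- **Regulator ranks**: per target, positions of true regulators in the local
  ranking, as rank percent `100·(m−r)/(m−1)`, summarized by median per
  in-degree.

## Synthetic data generator

The generator emulates the *structure* of multifactorial steady-state
experiments: every condition perturbs the basal activation of all genes
simultaneously by small independent amounts, the network settles, and the
state is measured with noise.

- Topology: each ordered non-self pair is an edge with probability
  `d/(p−1)` (expected in-degree d); effects have magnitude U(0.3, 0.8) with
  random sign — moderate sub-unit couplings that keep the linear dynamics
  well inside the stability region — and the weighted adjacency is rescaled
  to spectral radius ≤ 0.9 if needed. Cycles are allowed, self-edges are not.
- Conditions: basal level 1 per gene; per-condition per-gene shift
  N(0, 0.3²) ("slight" relative to basal); measurement noise N(0, 0.05²),
  a typical technical-noise scale. N defaults to 100 conditions.
- Steady states: the linear model `x = Ax + b` is solved in closed form
  (the residual is checked below 1e-8 in tests); the sigmoid model
  `x = σ(Ax + b)` is iterated to a fixed point (tol 1e-8, ≤200 iterations,
  per-condition retry with a fresh draw, up to 10).

**What passing the benchmark does and does not show.** The recovery
benchmark (p = 20, expected in-degree 2, N = 150, RF, T = 100, K = all;
5 seeds) demonstrates that the pipeline ranks true edges far above chance
(mean AUROC ≈ 0.76 versus 0.5 for shuffled rankings). It does *not*
demonstrate edge-direction recovery: a linear-Gaussian structural model is
Markov-equivalent under edge reversal, so forward and reverse conditional
dependencies carry identical information, and because a target's variance
accumulates its parents' variance, unit-variance normalization tends to make
the *reverse* weight (child predicting parent) slightly the larger one. The
direction-swap comparison is therefore expected to be a statistical tie (or
slightly reversed) on this generator — the directionality successes reported
on the original in-silico benchmarks relied on nonlinear kinetic simulations,
which this simple generator intentionally does not reproduce. Neither
steady-state model claims fidelity to detailed transcription kinetics
(mRNA/protein dynamics, Hill regulation, intrinsic stochasticity); results
on this generator bound what to expect from real data only loosely.

## Problem sizes used in the test suite

Test and acceptance runs use reduced problem sizes chosen to exercise every
code path while keeping the suite quick: ensembles of 5–200 trees on 4–150
samples, the recovery benchmark at p = 20 × 5 seeds × T = 100, and
Monte-Carlo checks at B ≤ 999. The defaults (T = 1000) match the method's
standard operating point and are used unchanged by the CLI.

## Known limitations

- Threshold selection on the ranking is out of scope: the method outputs a
  ranking, and choosing a cutoff is left to the user.
- Edges are unsigned; activator/repressor distinction is not attempted.
- Tree growth is O(T·K·N·logN) per target with Python/NumPy vectorized node
  operations — fine for hundreds of genes, but a p ≈ 4000 compendium at
  T = 1000 is a long run on one core.
- Missing values and raw-array preprocessing (log transforms, batch
  normalization) must be handled upstream.
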
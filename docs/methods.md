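# Methods

This note documents the model, the algorithms, the synthetic-data
generator, and the numerical and design choices behind `survsig`, at the
level of detail a maintainer or reviewer needs to judge what the tests do
and do not demonstrate.

## Regression model and fitness

The estimator is ν-support-vector regression with an RBF kernel
`k(u, v) = exp(−γ‖u−v‖²)`, solved by libsvm through scikit-learn's `NuSVR`.
In the ν parameterization the tube width ε is an optimization variable; ν
is simultaneously an upper bound on the fraction of samples outside the
tube and a lower bound on the fraction of support vectors. Survival times
are regressed directly in months; only uncensored (observed-death) samples
enter training.

The selection fitness is the Pearson correlation between the true survival
vector and the *pooled* out-of-fold predictions of a 10-fold CV. Pooling is
deliberate: at ~10 samples per fold, per-fold correlations are dominated by
noise, whereas the pooled statistic is a stable, monotonically improvable
target for a search algorithm. MAE on the same pooled predictions is
reported in months (divide by 12 for years).

Two determinism rules make the fitness a pure function of the chromosome:

* the fold partition is drawn once per run from `cv_seed` (sizes differ by
  at most one; e.g. 102 samples split as eight folds of 10 and two of 11)
  and reused for every evaluation in that run — a per-generation redraw
  would make fitness stochastic and break elitism;
* libsvm runs with an iteration cap (`max_iter = 10000`). Uncapped solves
  at the top of the C grid (C = 2¹⁰) take two orders of magnitude longer
  than typical fits while moving predictions only marginally; the cap
  bounds the cost of every fitness call and is itself deterministic.

Evaluations are memoized by (feature bits, hyper genes); a chromosome whose
predictions are constant (correlation undefined) receives fitness −∞ so it
can never be selected.

## Hyperparameter encoding

Three 4-bit genes map onto log-spaced grids:

| gene | parameter | grid | default rationale |
| --- | --- | --- | --- |
| g₁ | γ (RBF width) | 2^(g₁−15), i.e. 2⁻¹⁵…2⁰ | spans widths from near-linear to highly local for z-scaled features |
| g₂ | C (regularization) | 2^(g₂−5), i.e. 2⁻⁵…2¹⁰ | standard libsvm search range |
| g₃ | ν | (g₃+1)/16, i.e. 1/16…1 | full admissible interval (ν ≤ 1), zero excluded |

## The inheritable combinatorial GA

One run solves the whole family of subset problems C(n, r) for
`r = r_start..r_end`:

1. initialize `n_pop` random chromosomes with exactly `r_start` selected
   bits and random hyper genes;
2. per generation: tournament selection (size 2) into a mating pool;
   orthogonal-array crossover on `p_c·n_pop` parents (each pair replaced by
   the child and the fitter parent); popcount-preserving mutation on
   `p_m·n_pop` individuals sparing the best (one selected↔unselected bit
   swap, plus a 50% chance of re-randomizing one hyper gene); explicit
   elitism — the generation's best individual always survives;
3. after `g_max` generations the best individual is recorded as S_r; then
   every individual flips one random 0→1 ("inheritance") and the sweep
   moves to r+1;
4. the answer is the best S_r over the sweep, ties broken toward the
   smallest r (parsimony: the point of the method is a *small* signature).
   Fixed-size selection is expressed as `r_start = r_end = k`.

Population defaults (`n_pop=50, p_c=0.8, p_m=0.05, g_max=60, r=5..30`)
follow the conventional settings of the intelligent-evolutionary-algorithm
lineage this optimizer derives from; every value is config-exposed, and the
benchmark studies below use deliberately small configurations.

### Orthogonal-array crossover

Positions where the two parents differ are partitioned, in index order,
into at most 7 contiguous factors (differing hyper genes form one extra
factor; the cap keeps each crossover at ≤ 8 fitness calls). The canonical
two-level array L_N with N = 2^⌈log₂(k+1)⌉ rows is built in closed form —
entry(i, j) = 1 + popcount(j & bitrev(i)) mod 2, the Hadamard-derived
construction in Taguchi column order, so L4 = [[1,1,1],[1,2,2],[2,1,2],
[2,2,1]]. Each OA row defines a candidate child (factor level 1 = take
parent a's genes, level 2 = parent b's); per-factor main effects over the
evaluated candidates predict the best level of each factor, and the child
is the fitter of the predicted-best composite and the best evaluated
candidate, finally repaired to exactly r bits by uniformly chosen flips.
Candidates that are infeasible (e.g. an empty subset) enter the effect
estimate at slightly below the worst finite response, steering levels away
from them. On additively separable fitness functions the composite provably
equals the global argmax over all 2^k factor combinations, which the test
suite verifies against brute force; repair can be disabled
(`target_popcount=None`) precisely so that check is exact.

The factor grouping is contiguous-in-index because the crossover requires
*a* deterministic grouping, not a specific one; any fixed partition
preserves the main-effect logic.

## Appearance score

R independent runs (same cohort, same CV partition, different GA seeds)
yield R signatures. The appearance frequency of feature p is
`f(p) = (#runs containing p) / R`, and run t scores
`S_t = (1/m_t) Σ_i f(p_i)` over its m_t features, so `S_t ∈ (0, 1]` and
S_t = 1 iff every feature of run t appears in all runs. The run with
maximal S_t is kept (ties → earliest run index). Normalizing by R makes the
score read as an average selection probability. R defaults to 30;
benchmarks use 10.

## Main effect difference (MED)

For a chosen m-feature signature, the smallest two-level OA with m columns
(N = 2^⌈log₂(m+1)⌉ rows — e.g. N = 32 for m = 18) defines N
include/exclude patterns. Each row's response is the CV correlation using
only the included features, with the signature's hyperparameters and its
run's fold partition — re-tuning per subset would confound feature
contribution with hyperparameter drift, so both are held fixed. Rows whose
included set is empty have no predictor and score 0. A feature's MED is the
absolute difference between its mean response at level 1 (included) and
level 2 (excluded); features are ranked by descending MED. MED is reported
in fitness (correlation) units. The OA estimate aliases interaction effects
into main effects — MED is a ranking heuristic, not an ANOVA.

The per-feature *individual effect* is complementary: a 16×16×16 grid
search (coarsenable via `gene_values`) over the decoded hyperparameter grid
for the best single-feature ν-SVR, reporting its CV CC and MAE.

## Censored-cohort validation

Test cohorts contain only censored (alive) patients, whose follow-up time
is a lower bound on true survival. The final model (trained on the full
training cohort with the selected features) predicts each test patient;
the report carries the per-patient (follow-up, prediction) table, the
fraction of patients with prediction > follow-up, and mean ± SD of both in
months. A high fraction is *consistent with* — not proof of — unbiased
predictions, since any upward-biased predictor also scores high; the
synthetic tests therefore compare against the generative ground truth
rather than treating the fraction as sufficient evidence.

## Baselines

All baselines share the GA's fold partition and pooled-CC criterion:

* **Stepwise MLR** — forward addition; at each step the feature whose OLS
  fit maximizes CV CC joins the model; stops when no candidate improves CC
  or `max_features` is reached. The stop rule is CV-improvement (not
  AIC/p-values) so all methods optimize the same currency. OLS uses an
  orthogonal-decomposition solve; rank-deficient candidates are skipped.
* **Elastic net** — objective `(1/2M)Σ(y_i − β₀ − x_iᵀβ)² + λP_α(β)` with
  `P_α(β) = α‖β‖₁ + (1−α)‖β‖₂²/2`, which is exactly scikit-learn's
  `ElasticNet(alpha=λ, l1_ratio=α)`; λ is chosen from a grid (default 50
  log-spaced values 10⁻³…10²) by CV CC, α defaults to 0.5. α = 1 is the
  LASSO; α = 0 is solved by the ridge closed form
  `(XᵀX + MλI)⁻¹Xᵀy` on centered data, and λ = 0 reduces to OLS — both
  limits are verified against independent solvers in the tests.
* **compare_methods** additionally runs the GA at each baseline's selected
  feature count for a same-size comparison.

## Synthetic cohorts

The generator plants a sparse linear signal: X is i.i.d. standard normal
(M × n), s planted features (chosen uniformly at random, returned in
effect-size order) carry effects β (months per expression unit), and

    y* = baseline + Σ_j β_j x_j + N(0, noise_sd²),  clamped below at 1 month.

A `censor_fraction` subset is emitted as alive with follow-up drawn
uniformly in (0, y*), so censored follow-up strictly underestimates
survival by construction. The clamp (rather than resampling) keeps the
generator a fixed-draw function of the seed; at the default baseline of 60
months the clamp is ~6 SD below the mean and its bias is negligible.

Standard benchmark conditions: M = 150, n = 40, s = 4, β = (6, 5, 4, 3),
noise_sd = 2, baseline = 60. What the generator does *not* emulate:
RNA-seq count noise, feature–feature correlation, nonlinear survival links,
or informative censoring. Passing tests therefore demonstrate that the
machinery recovers a recoverable signal and ranks it sensibly — not that
any particular real-data signature is correct.

## Study sizes used by the test suite and acceptance script

* **Exhaustive-search check**: M = 60, n = 12, r = 3 fixed, hyper genes
  fixed at (8, 10, 7); the GA (pop 10, 8 generations, 10 seeds) is compared
  against the brute-force maximum over all 220 subsets.
* **Pipeline study**: five replicate cohorts at the standard benchmark
  conditions, each analysed by a 10-run consensus ensemble with a small GA
  (pop 12, 6 generations, subset sweep 2..5), followed by MED ranking and a
  censored validation on a fresh 60-sample all-censored cohort from the
  same generative model.
* **Baseline comparison**: M = 80, n = 15, s = 3, with a moderately larger
  GA (pop 16, 12 generations) since the hyperparameter genes need enough
  generations to locate the high-C/low-γ corner that makes the RBF model
  competitive with linear fits on linear data.

These sizes are the package's benchmark definition; all are plain
`GAConfig`/`SimulationSpec` values and scale up by changing the config.

## Numerical choices and edge cases

* Day→month conversion uses 30.44 days/month; months are the internal unit,
  years only appear in summaries (1 year = 12 months).
* The canonical clinical TSV written by `write_cohort` carries a
  full-precision `survival_months` column beside an integer `days` column;
  the reader prefers it, and parses with pandas' round-trip float mode, so
  write→read preserves times bit-exactly.
* Duplicate patient rows keep the first occurrence (logged); missing
  expression values are an error, not imputed; expression is used as
  provided, with an optional per-feature z-scaling switch (default off)
  for data whose scale is unknown.
* Pearson correlation raises on constant inputs rather than returning NaN;
  its output is clipped into [−1, 1] against rounding overshoot.
* `repair` flips uniformly chosen bits, so crossover children violating the
  popcount constraint are corrected without positional bias (verified by a
  chi-square test over repeated draws).
* Mutation cannot change r; the inheritance step is the only place the
  subset size grows.
* Result files (signature JSON, feature TSV, manifests) contain no
  timestamps, so identical seeds reproduce byte-identical outputs.

## Known limitations

* Censoring is handled by exclusion (training) and bound-checking
  (validation), not by a likelihood; the method is not a survival model in
  the Cox/AFT sense.
* MED values depend on the chosen hyperparameters and fold partition; they
  rank features within one signature and are not comparable across runs.
* The appearance score measures stability of the search, not biological
  truth; with too few runs it can concentrate on a locally attractive
  decoy set.
* The OA crossover's factor grouping is one of many valid choices; with
  strongly interacting distant genes a different grouping could recombine
  better.
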
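# Methods

## Model and assumptions

`multifactv` fits a rank-`K` CP decomposition of a dense third-order
tensor `A` (entity1 × entity2 × time; canonically gene × condition ×
time) with an L1 total-variation penalty on the time factors:

```
min  ||A − Σ_k u_k ∘ v_k ∘ w_k||_F² + α Σ_k ||B w_k||₁
s.t. W ≥ 0, 1ᵀ w_k = 1,
```

with `B` the (n3−1)×n3 first-difference matrix. The model assumes the
third axis is chronologically ordered (TV is meaningless otherwise) and
the tensor is fully dense; missing values must be resolved at I/O time.
No sign assumption is made on the data or on `U`, `V` — only the time
profiles are constrained, to the probability simplex, which makes each
`w_k` interpretable as a normalized activity profile and pins down the
scale/sign indeterminacy of the CP model on the time axis (the remaining
joint sign flip of `(u_k, v_k)` is handled at extraction).

All mode unfoldings use the "earlier retained mode varies fastest" column
order, the unique convention under which `A⁽¹⁾ = U (W ⊙ V)ᵀ`,
`A⁽²⁾ = V (W ⊙ U)ᵀ` and `A⁽³⁾ = W (V ⊙ U)ᵀ` hold with `⊙` the column-wise
Kronecker (Khatri-Rao) product.

## Optimization

Block-coordinate descent over `U`, `V`, `W`:

1. `U ← A⁽¹⁾Fᵀ(FFᵀ)⁻¹`, `F = (W ⊙ V)ᵀ`, computed from the previous
   iteration's `V`, `W`;
2. `V ← A⁽²⁾Fᵀ(FFᵀ)⁻¹`, `F = (W ⊙ U)ᵀ`, using the *fresh* `U` and the
   *previous* `W` (deliberate Gauss–Seidel ordering);
3. `W` by ADMM on the TV-split problem with auxiliary `P ≈ BW` and
   scaled dual `Q`:
   `vec(W) ← (FFᵀ ⊗ 2I_{n3} + ρ I_K ⊗ BᵀB)⁻¹ vec(ρBᵀ(P − Q/ρ) + 2A⁽³⁾Fᵀ)`,
   `P ← shrink_{α/ρ}(BW + Q/ρ)`, `Q ← Q + ρ(BW − P)`.

`FFᵀ` is always formed as the Hadamard product of the two small Gram
matrices, so the only large operation per update is the
matricized-tensor-times-Khatri-Rao product. The Kronecker system for `W`
(n3·K ≤ a few hundred in all intended uses) is assembled densely and
LU-factorized once per outer iteration; each inner ADMM step is then a
pair of triangular solves.

Numerical choices:

* **Initialization.** `U`, `V` i.i.d. normal scaled by
  `||A||_F / (K·√(n1·n2))` (matches the data's energy scale and avoids
  early blow-up); `W` uniform positive, columns normalized. `P`, `Q` are
  re-randomized from the seeded generator at the start of every outer
  iteration — a cold ADMM start kept for faithfulness to the original
  procedure; warm starts would be a one-line change.
* **Inner stopping.** The ADMM loop stops when both the iterate change
  `||W_s − W_{s−1}||_F` and the primal residual `||BW − P||_F` fall
  below `inner_tol` (default 1e-6), or after `inner_max_iter` (default
  200) iterations.
* **Constraint enforcement.** The inner loop is the exact unconstrained
  fixed-point iteration; the simplex constraints are imposed once, after
  the loop: negatives clipped to zero, columns L1-normalized, an
  all-zero column reset to the uniform profile with a warning. The next
  `U`/`V` updates absorb the rescaling.
* **Outer stopping.** `||ΔU||² + ||ΔV||² + ||ΔW||² ≤ 0.001` (raw sums,
  not size-normalized), capped at `outer_max_iter` (default 100).
* **Degeneracies.** A near-singular `FFᵀ` (collinear factor columns,
  condition number > 1e12) gets a 1e-10 ridge and a warning; a singular
  ADMM system raises.
* **ρ and large α.** ρ defaults to 1. The ADMM dual must grow to
  O(α/ρ), so in the TV-dominated regime (α ≫ 1) ρ should be scaled with
  α or the inner iteration cap raised; with ρ ≈ α the solver reaches the
  flat-profile fixed point in a handful of iterations.

The exact `U`/`V` updates cannot increase the residual term;
the `W` projection can, so the objective trace is monitored rather than
asserted monotone. In practice it decreases to a plateau within a few
tens of iterations.

## Module extraction

Per column `k`: flip `u_k` (and independently `v_k`) when its positive
entries sum to less than the magnitude of its negative entries; then keep
gene `r` iff `u_{r,k} ≥ 0.5·τ1·(max(u_k⁺) + min(u_k⁺))`, and likewise
conditions with `τ2`. Time points use the full column:
`w_{t,k} ≥ 0.5·τ3·(max(w_k) + min(w_k))` (valid since `W ≥ 0`). Ties at
the threshold are kept (`≥`).

One deliberate reading: the `min` in the gene/condition rule is taken
over the *nonnegative* entries. On any noisy or real data this is
identical to the minimum over strictly positive entries (exact zeros do
not occur); on clean synthetic data, where entities with no support have
loadings of exactly zero, it keeps the threshold at half the column
maximum instead of letting the smallest true member define it — without
this, noiseless recovery is structurally impossible at `τ = 1`. A column
with no strictly positive entry contributes an empty set; such modules
are flagged `degenerate` but never dropped, so module indices stay
aligned with factor columns. Whether each time set is a contiguous run is
reported (`time_contiguous`) but not enforced — the TV penalty only
encourages contiguity.

Default thresholds: `τ1 = τ2 = 1.0`, `τ3 = 0.75` (synthetic preset); the
CLI also ships `yeast` (0.75/0.85/0.75) and `human` (0.5/0.5/0.75)
presets for the corresponding real-data regimes.

## Synthetic benchmark

`generate_planted_tensor` plants `K` modules — a gene set × condition set
× consecutive time interval — of i.i.d. `Uniform(0.6, 1.0)` signal on a
zero background, then overwrites a fraction `noise_density` of *all*
cells (uniformly chosen, without replacement) with draws from the same
distribution. Defaults mirror the full-scale benchmark: 400×400×50,
40 genes and 40 conditions per module, 10-point intervals, densities
0.005/0.01/0.02. Gene and condition sets are disjoint across modules by
default. Time intervals are placed disjointly whenever
`K·interval_length ≤ n3` (so the ground truth is a clean partition — the
regime the partition-based NMI assumes) and at independent random starts
otherwise, which is unavoidable for `K ∈ {8, 10}` at `n3 = 50`; both
behaviors are overridable via `time_placement`. Dense additive Gaussian
noise is available behind `gaussian_noise_sd`.

What this generator does *not* emulate: real expression value
distributions (heavy tails, correlated baseline structure), modules with
overlapping gene sets, condition-specific response shapes within a
module, or temporal autocorrelation in the background. Passing the
benchmark therefore demonstrates correct recovery of well-separated
block structure under sparse corruption — not performance on real
profiling data.

## Evaluation conventions

Modules are compared as element sets over three disjoint namespaces
(`gene:`, `cond:`, `time:`).

* **Fscore**: per-pair set F1, maximum-weight one-to-one assignment
  (Hungarian algorithm) between found and truth modules, mean F1 over
  truth modules; unmatched truth modules contribute 0.
* **NMI**: each side becomes a hard labeling of the full element
  universe — module index, or a shared background label; an element
  claimed by several found modules goes to the one with the largest
  factor value (strategy `"score"`, default) or the lowest index
  (`"first"`). Normalization is geometric,
  `I(X;Y)/√(H(X)H(Y))`. If both labelings are constant the value is 1
  when they agree and 0 otherwise.

These conventions (matching scheme, background label, √ normalization,
overlap resolution) are package decisions — standard but not uniquely
determined — so published benchmark scores are reproduced within a
tolerance band rather than digit-for-digit.

## Problem sizes and defaults used in shipped runs

The acceptance/benchmark protocol runs the full 400×400×50 tensors with
5 random restarts per setting and keeps the best-objective run; one
setting takes tens of seconds on a single CPU (the dominant cost is the
three MTTKRP products per outer iteration, ~2·n1·n2·n3·K flops each).
Unit and property tests use 20–60-sized axes, where a fit completes in
well under a second.

## Known limitations

* Third-order tensors only; no Tucker variants, no sparse storage.
* The outer objective is not guaranteed monotone (simplex projection
  after the ADMM loop), and block-coordinate descent only reaches local
  minima — restarts are the mitigation.
* The inner ADMM converges slowly when `α/ρ` is very large (see above).
* Recovery on the 10-module high-noise benchmark is substantially
  *better* than the historically published figures for this protocol;
  the planted instances here, with disjoint 40×40 blocks and bounded
  uniform noise, are easier than whatever (unpublished) generator
  produced those figures. Comparisons against them are qualitative.
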
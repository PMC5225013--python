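# Methods

`gpkin` models short-term saturable transport — concretely, apical iron
uptake by Caco-2 monolayers in bicameral inserts — by symbolic regression:
a genetic-programming (GP) search over closed-form expressions in the
initial apical concentration `C0` (µM) and time `t` (min), scored not by
training error but by a leave-one-out estimate of generalization error.
This note records the model, the algorithmic and numerical choices, and the
known limitations, including a quantitative account of why two published
statistics of the reference models cannot be recovered from their printed
parameter digits.

## The search

**Genotypes.** Rooted expression trees over the function set
`cos, sin, +, −, *, /, a^b, ln, exp` and terminal set `{C0, t}` ∪
`{1, 5, 10, 100, 1000}`. Arity is enforced structurally; tree depth is
capped at 28 levels. Power is real-valued: a negative base with a
non-integer exponent yields NaN. Division by zero, `ln(x ≤ 0)` and `exp`
overflow propagate as non-finite values — there are no "protected"
operators. Models that are singular inside the experimental domain are
removed later by curation, which matches how a practitioner screens
symbolic-regression output and avoids biasing the search toward expressions
that only work because an operator was silently patched.

**Lamarckian refitting.** Before an individual is scored, every numeric
constant in its tree is lifted to a parameter slot (depth-first,
left-to-right: `b1, b2, …`), the vector β is refit to the training data by
local optimization, and the improved constants are written back into the
genotype, so good parameterizations are inherited. Fitting minimizes either
the sum of squared residuals (`l2`, default) or the sum of absolute
residuals (`l1`); both forms are implemented because conventions in the
source literature for this problem are genuinely ambiguous (an objective
*named* mean-square error but *written* with absolute values and no 1/N).
Discriminating the two empirically requires the replicate-level training
table, which is not distributed with the package, so the default stays
`l2` and fitted parameters should be compared across objective forms when
it matters. Optimization is Levenberg–Marquardt on residuals for `l2`
(trust-region reflective when observations do not outnumber parameters) and
Nelder–Mead for `l1`, starting from the tree's own constants plus
log-uniformly perturbed restarts (default 5 for standalone fits, 2 inside
the GP fitness loop, where each individual already costs N+1 fits).
Convergence tolerances are 1e-12 on the objective and 1e-10 on parameters,
tight enough that reported optima are optimizer-independent at three
significant figures.

**Fitness.** The jackknife (leave-one-out) generalization error: for each
of the N training observations, refit β on the other N−1 points
(warm-started at the full-data optimum) and accumulate the held-out
prediction error, squared by default (`l1` aggregation available,
mirroring the objective choice). Individuals non-finite on the data, or
with more parameters than observations, receive a worst-rank sentinel
(+∞) rather than being deleted, which keeps the population size constant
under the generational scheme. Fitness values are cached by genotype
string; converged populations are dominated by duplicates and the cache is
the single biggest cost lever.

**Evolution.** Generational loop with ramped-half-and-half initialization
(depths 2–6, alternating full/grow construction), tournament selection
(size 2 — the selection method is standard but its size was an open choice;
2 is the weakest standard pressure and pairs well with elitism), subtree
crossover with probability 0.9, subtree mutation with probability 0.1
(replacement subtree grown to depth ≤ 4), and keep-the-best elitism.
Offspring exceeding the depth limit are rejected and the parent survives.
Termination is a fixed generation count (no early-stop threshold). The
defaults — population 500, 50 generations — are the standard configuration
for this problem class; the test suite and the planted-recovery acceptance
property run reduced sizes (population 25–60, 4–30 generations, N = 9
noise-free observations), chosen as the smallest problem sizes at which
the recovery property is reliably exercised, since the jackknife fitness
makes every individual cost N+1 nonlinear fits.

Fixed seed ⇒ bitwise-identical run archives; multi-run searches spawn
per-run seeds deterministically from the root seed (kept below 2^31).

## Inference and assessment

**Pseudo-value inference.** The same N leave-one-out refits give, per
parameter k, pseudo-values `pv_i = N·β_k − (N−1)·β_{i,k}`, the bias-reduced
estimate β*_k (their mean), its standard error
`sqrt(Σ(pv_i − β*)² / (N(N−1)))`, confidence intervals
`β* ± t_{α, N−k}·se` with α = 0.05, and two-sided t-tests of β* = 0 on
N−k degrees of freedom. (The source's standard-error display omits an
explicit square root; it is implemented as the standard jackknife SE, the
only reading consistent with its use in the CI.)

**R² and AICc.** R² = 1 − SSE/SST about the observation mean (may be
negative). AICc uses the least-squares form
`N·ln(SSE/N) + 2k + 2k(k+1)/(N−k−1)`; no formula was printed for the
reference models, so AICc values are comparable only within this package's
cohorts, and reproduction of published AICc magnitudes is not attempted.

**Curation.** Per-run best models are screened on the declared domain
(t ∈ [0, 15] min, C0 ∈ [0, 20] µM; 0.1-step grid plus 10⁴ seeded random
interior points): training R² ≥ 0.8, finite everywhere (singularity
screen), and non-negative predicted uptake. Verdicts report the first
violated rule; the screen is order-independent. Best-model selection is
configurable between minimum generalization error (default, applied after
curation) and maximum training R², because the source procedure states
both criteria in different places; the discrepancy is surfaced rather than
resolved.

**Decomposition.** After fixing one variable, the model is expanded into
top-level additive components grouped by character (constant, linear,
quadratic, exponential-in-t, sinusoidal-in-C0, …), with the invariant that
components sum to the full model at every query point (checked at 1e-9
relative). Shares at a query point are |component| / |total|.

**Domain scan.** The initial rate is defined operationally as 3-min uptake
divided by 3 min, converted from pmol/insert to µM/min via the
cellular+basolateral volume V_c+b = 1000 µL (1 µM ≡ 1000 pmol). A dense
grid over the concentration range (default 4001 points on [0, 100] µM)
locates the rate maximum, a bounded scalar minimizer polishes it, and the
first downward zero crossing beyond the maximum is solved by bracketing.

## Units and the kinetic baselines

Uptake is stored in pmol/insert, rates in µM/min referred to V_c+b.
The Michaelis–Menten / Hill rate law is
`v = Vmax·C^n / (Km^n + C^n) · (Va/Vcb) + b` with Va = 200 µL,
Vcb = 1000 µL, Hill n = 1 for MM, and an optional basal-leak offset b
(default 0: the published parameter tables list only Km, Vmax and n, so
the trailing term in the typeset rate law is read as the volume subscript,
not an offset; the offset remains available for users who want a leak
term). Because apical depletion over 15 min is negligible, uptake curves
integrate the rate at constant substrate: `uptake = rate(C0)·t·Vcb`. Four
fitting variants mirror the published comparison: both parameters free;
Km pinned at the literature value 7 µM; Km pinned at a measured value
(e.g. 10.36 µM from 3-min initial rates) with Vmax free; and the
three-parameter Hill fit.

## The synthetic generator

`ExperimentDesign` emulates the insert assays: a training design of
C0 ∈ {5, 10, 20} µM × t ∈ {3, 6, 9, 12, 15} min × 3 replicates (the assay
is described as triplicate measurements between 3 and 15 min; five evenly
spaced timepoints were fixed once) and a rate design of
C0 ∈ {3, 5, 7, 10, 20} µM at t = 3 min × 3 replicates. Noise is
multiplicative Gaussian, `observed = prediction · (1 + ε)`,
ε ~ N(0, cv), default cv = 0.2 — chosen once as realistic for Caco-2 flux
assays, whose error bars grow with the mean and whose between-culture
variability is large. The generator does **not** emulate: correlated
replicate structure within a culture, heteroscedasticity beyond the
multiplicative form, censoring at detection limits, or apical depletion at
long times. Passing tests on generated data therefore demonstrate
correctness of the estimators and the search under the stated noise model,
not robustness to every feature of real flux data.

## Reproducibility of the published reference models

`gpkin.reference_models` transcribes the two published uptake models:

    best:   ApUp = b1·C0 − sin(b6)·t·C0·(C0 + b3 + sin(C0·exp(b2)) − b5·t·b4^t)
    pruned: ApUp = b1·C0 − sin(b6)·t·C0·(C0 + b3 − b5·t·b4^t)

with parameters printed to three significant figures. Two of those digits
sit in catastrophically sensitive positions:

* **b6 = 1.01×10²** enters only through `sin(b6)` (radians, unreduced) and
  lies next to a zero of sine: 32π = 100.5310 also prints as 1.01×10².
  Taken literally, sin(101.0) = 0.452 and the pruned model predicts
  ~1.9 nmol/insert of uptake at (20 µM, 3 min) — about half of all iron
  present in the apical compartment, two orders of magnitude above the
  scale implied by the companion Michaelis–Menten fits, and incompatible
  with the published training R² of 0.854. Inverting the published
  rate-maximum location (48 µM) instead gives sin(b6) ≈ 6.6×10⁻⁴, i.e.
  b6 ≈ 32π + 6.6×10⁻⁴ = 100.5316 — which both prints as 1.01×10² and
  *exactly* reproduces the published zero crossing at 96 µM, and whose
  scale matches the published confidence half-widths for b6 (±3.9×10⁻⁴ /
  ±9.1×10⁻⁴). The published 48/96 µM figures therefore live in a digit of
  b6 that the tables do not print. The package does not substitute the
  reconstructed value; the faithful computation from the printed digits
  gives a rate maximum at 45.79 µM and a zero crossing at 91.57 µM
  (the two locations differ from the reconstruction only through the small
  b1/sin(b6) offset; their ratio-of-2 geometry is preserved).
* **b2 = 2.15×10²** appears as `sin(C0·exp(b2))` with
  exp(215) ≈ 1.8×10⁹³: the sine's value changes completely when b2 moves
  in its *sixteenth* significant digit, so the printed three digits cannot
  pin it. Worse, float64 itself cannot represent the argument to within
  many multiples of 2π — rounding exp(215) to 53 bits perturbs the phase
  by ~10⁷⁸ rad — so the only well-defined evaluation of the *printed*
  expression treats the printed decimals as exact rationals and reduces
  the argument in arbitrary precision. Decomposition component values are
  therefore computed symbolically (sympy, 50 digits); under that
  convention the sinusoidal component at C0 = 20 µM, t = 3 min carries
  0.696 % of the total, against a published 0.96 % (plain float64
  evaluation would give 0.284 %). All three numbers agree that the
  sinusoid is sub-1 % and prunable, which is the scientific conclusion the
  share supports.

Everything in the reference models that does not pass through these two
sines — the pruned/best structural relationship, the decomposition
additivity, the ratio-of-two geometry between the rate maximum's offset
and the zero crossing's offset, C0 = 0 annihilation — is reproduced
exactly and covered by tests.

## Other numerical choices

* Serialization uses a canonical infix grammar with explicit parentheses;
  `parse(serialize(x))` is structurally exact, and unary minus is folded
  into numeric literals so trees never carry a negation operator.
* Tournament ties break toward the smaller tree, then a random draw — a
  mild parsimony pressure that also makes selection deterministic under a
  seed.
* The non-finite-residual sentinel is 10²⁰: large enough to dominate any
  physical residual, small enough that its square and finite-difference
  Jacobians stay inside float64.
* Leave-one-out refits warm-start from the full-data optimum and fall
  back to perturbed restarts on failure; failed iterations are recorded in
  the report rather than silently dropped.
* R² requires non-constant observations and raises otherwise; AICc
  requires N − k − 1 > 0.

## Known limitations

* The GP search at full published scale (population 500 × 50 generations
  × 50 runs with a 45-observation jackknife fitness) is hours of CPU; the
  shipped tests exercise the identical code path at reduced scale.
* No algebraic simplification beyond additive-branch pruning; structurally
  distinct but algebraically equal genotypes count as different in variety
  and conservation statistics.
* The constant-substrate uptake integration restricts model validity to
  times where apical depletion is negligible, exactly as in the assays.
* p-values for pseudo-value t-tests are nominal: they assume approximate
  normality of pseudo-values, which is untestable at N this small.
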
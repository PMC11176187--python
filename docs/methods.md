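# Methods

## The model

A Boolean network on n nodes assigns each node i an update rule
f_i: {0,1}^k → {0,1} over an ordered list of regulators. We consider only the
synchronous map F(x) = (f_1(x), …, f_n(x)); each state therefore has a unique
successor, and every trajectory ends on an attractor (a fixed point or limit
cycle). The *wiring diagram* contains an edge i → j exactly when f_j depends
*essentially* on x_i, i.e. flipping x_i changes f_j for at least one context.
Listed-but-inert regulators are excluded from the wiring and stripped by
`reduce_to_essential` before any comparison between rules.

Truth tables are stored as flat 2^k bit vectors with x_1 as the most
significant index bit. This single convention is used everywhere: rule files,
state-space codes, and polynomial subset masks, so objects round-trip without
reindexing.

## Canalization

f is canalizing if some variable x_i has an input a that forces the output to
b regardless of all other inputs. Peeling all currently-canalizing variables,
restricting each to its non-canalizing input, and recursing yields the
standard monomial form: layers (k_1, …, k_r) of simultaneously canalizing
variables, a flattened cascade (σ, a_i, b_i), and a non-canalizing core. The
total number of peeled variables is the canalizing depth; depth = k makes the
function nested canalizing (NCF). Two structural facts the code relies on
(and the tests verify by brute force):

* all variables canalizing at the same stage share their canalized output, so
  a layer has a single b;
* depth k−1 is impossible (a 1-variable core is always canalizing), so exact
  depth-(k−1) requests fail loudly rather than being silently bumped to k.

Conventions where the mathematics leaves a choice: constant functions are by
default *not* canalizing (a flag flips this for the probability-of-
canalization grids, where the common presentation counts them); the all-zero
function, which has no standard monomial form, gets a convention report of
depth k flagged `is_constant`; a lone remaining identity/negation variable
records its a = 0 witness. An NCF is required to have depth equal to its full
listed arity — a degenerate function is never an NCF, which matches the
enumeration fact that exactly 8 of the 16 two-input functions qualify.

### Constrained generators

All generators take an explicit `numpy.random.Generator` and verify nothing
silently: infeasible requests raise, and rejection sampling is capped at
10^5 attempts with a deterministic error.

* `random_with_exact_depth(k, d)` — random cascade frame (uniform variable
  subset, order, inputs; independent uniform outputs b_i) over a random
  non-canalizing, fully essential core. The cascade variables are canalizing
  by construction and a non-canalizing core never adds depth, so the realized
  depth is exactly d.
* `random_with_exact_depth_and_bias(k, d, q, b_1..b_d)` — as above but with a
  prescribed output sequence; the cascade step i covers 2^(k−i) states, so
  the core must carry q − Σ_{b_i=1} 2^(k−i) ones, sampled with
  `random_function_exact_ones` plus rejection to non-canalizing/
  non-degenerate. Arithmetically impossible combinations raise.
* `random_with_min_depth(k, d)` — the core is a free non-degenerate function
  and may itself be canalizing, so the realized depth can exceed d (d = 0
  reduces to an unrestricted non-degenerate draw).
* `random_ncf_with_layers(k, (k_1..k_r))` — canalized outputs constant within
  a layer and alternating between layers, which is exactly what keeps the
  requested boundaries intact in the standard monomial form; σ and the a_i
  are uniform (the literature does not pin down a canonical distribution
  here; uniform is the natural choice and is stated, not hidden).
* `random_ncf(k)` — the exact-depth cascade at d = k with independent uniform
  b_i. Under this distribution the layer structures (4), (1,3), (2,2),
  (1,1,2) each arise with probability 1/4 at k = 4 and the mean average
  sensitivity is exactly 1, the calibration the acceptance checks assert.

## Dynamics metrics

Exact mode enumerates the 2^n-state successor table (cap n ≤ 20) and assigns
every state to a basin; sampled mode follows trajectories from distinct
random initial states (all states when 2^n does not exceed the request —
sampling is without replacement) until a state repeats, measuring the cycle
between the first and second visit. Attractors are identified by the
lexicographically minimal rotation of their cycle. Reported metrics: the
attractor count s (a lower bound in sampled mode), mean length (1/s)ΣL_i,
steady-state proportion (1/s)Σ1(L_i=1), their basin-weighted variants, and
the basin entropy −Σ (B_i/N) ln(B_i/N). The network-level robustness measure
is the mean over rules of the average sensitivity Σ_i Pr[f(x) ≠ f(x ⊕ e_i)]
(the Derrida coefficient); random (k, p) rules average 2kp(1−p), NCFs
average 1.

A network with c external parameters (nodes with rule f_i = x_i) decomposes
into 2^c disconnected state spaces; `attractors_per_external_configuration`
reports the exact attractor count divided by 2^c, which is ≥ 1.

## Continuous approximation and the MAE

The multilinear extension of f is the unique square-free polynomial on
[0,1]^k interpolating f on the hypercube vertices. It is stored in the basis
of centred monomials Π_{i∈α}(x_i − 1/2), computed by an axis-by-axis
(mean, difference) transform; the empty-set coefficient is the output bias.
The order-m Taylor polynomial around (1/2, …, 1/2) is simply the restriction
to |α| ≤ m: for a square-free polynomial the multi-index factorial is α! = 1,
so exact re-expansion — verified by vertex agreement — is the correct
reading, and m = k returns the extension itself. All coefficients and
evaluations at binary states are dyadic rationals, hence *exact* in double
precision: order-K networks reproduce the Boolean trajectory bit for bit and
their MAE is exactly 0.0, with no tolerance needed.

The continuous network applies the per-node truncations of the
essential-reduced rules, clipped to [0,1], synchronously. The mean
approximation error runs the Boolean and the continuous systems for a fixed
number of steps (default 25) from shared random initial states (default
1000, without replacement) and reports the mean squared per-coordinate
difference of the final states. The per-coordinate normalization (divide by
n) is deliberate: it gives the interpretable ceiling of 0.25, the signature
of a continuous system stuck at 1/2 against an effectively random Boolean
state. The fixed-horizon comparison knowingly inherits a time-shift
artifact: two systems can reach the same attractor out of phase and still
show a positive MAE. Within one experiment the same initial states serve all
approximation orders (variance reduction), and the Boolean trajectory is
computed once.

## Null models

Four rule-randomizations of a reference network, all preserving the
essential wiring: unconstrained (non-constant random function of the same
degree), type 1 (+ ones-count, via a uniform random subset Ω of size q),
type 2 (+ exact canalizing depth, arbitrary bias), and type 3 (degree, depth,
canalized-output sequence and core ones-count, hence bias). Matching is
always against the essential-reduced rule. External parameters are copied
unchanged (never replaced by the equally-constrained negation ¬x_i), and
constant rules, having no degrees of freedom, are copied too. Type 1 and the
unconstrained model impose no non-degeneracy by default — the type-1
distribution is genuinely uniform over the size-q subsets — and a
`require_nondegenerate` flag provides the stricter variant. Every ensemble
returns a provenance table with the per-rule realized (k, q, d) so the
constraints can be audited rather than assumed.

## Random ensembles (the synthetic data)

The Kauffman-style families place K distinct non-self regulators per node
and regenerate the wiring from scratch until it is strongly connected
(preserving the uniform conditional distribution; local rewiring would not).
Rules are drawn i.i.d. per family: biased random, non-degenerate random,
minimal-depth cascades, or layer-constrained NCFs. Study conditions follow
the experimental design throughout: N = 15, K ∈ {2,3,4,5}, p ∈ {0.1,…,0.5},
1000 initial states, 25 steps; duplicates across replicates are allowed.

The pseudo-biological generator stands in for curated regulatory-network
models where a corpus of real models is not bundled: in-degrees from a
shifted Poisson with mean ≈ 2.5 truncated to [1, 10], a 0.95 fraction of NCF
rules, the remainder non-degenerate unbiased, plus a configurable number of
external parameters; self-regulation is allowed. It reproduces the broad
statistics that drive the method (sparsity, canalization enrichment,
decoupled state spaces) but none of the curated models' motif structure,
signed interactions, or degree-bias coupling — results on it demonstrate the
pipeline, not biology. Real models in the plain-text rule dialect can be
dropped in through `read_rules`.

## Statistical layer

Spearman screens use average ranks for ties; constant columns produce NaN
with a warning, never a silent zero. Paired comparisons use the two-sided
Wilcoxon signed-rank test with zero differences discarded, and an all-zero
difference vector is flagged degenerate. No multiple-testing correction is
applied; tables report raw p-values. The LASSO minimizes
(1/N)‖y − Xβ‖² + α‖β‖₁ by cyclic coordinate descent on standardized inputs
(unstandardized input is an error, not silently rescaled); note the 1/N
scaling, which doubles the α axis relative to scikit-learn's 1/(2N)
convention and puts the all-zero threshold at 2·max_j|x_jᵀy|/N. Paths run
down a log-spaced grid (120 points, 3 decades) from that threshold and stop
when a ninth predictor activates; solutions satisfy the subgradient
stationarity conditions to 10⁻⁸. Feed-forward loops are raw ordered-triple
counts (i→j→k with i→k); coherence classification would need edge signs,
which plain truth tables do not carry, and is an extension hook. Feedback
loops are simple directed cycles of length 3 and 4.

## Problem sizes

The analysis scripts and the reproduction script use desk scales chosen as
the package's defaults: 10–20 networks per condition (the grid experiment
uses 20 per (K, p) cell, i.e. 400 networks), 300–1000 initial states, 25
steps, 1000 functions for sensitivity calibrations. The test suite uses 5
networks per grid cell with 500 initial states. Structural claims (exact
zeros, design fractions) are scale-free; stochastic quantities at these
scales carry sampling errors well inside the tolerances asserted.

## Known limitations

Exact attractor analysis is capped at n ≤ 20; sampled mode underestimates
attractor counts for chaotic networks. The MAE's fixed-horizon, phase-
sensitive comparison is inherited by design. Effective-connectivity and
canalizing-strength measures, signed-FFL classification, phenotype-aware
robustness variants, and asynchronous update schemes are out of scope.
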
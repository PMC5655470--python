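# Methods

## Model

The state N(t) is a population density; time is measured in years. The
right-hand side

    V(t, N) = a N² − b N − (1 − p) v(t) N²
            = [a − (1 − p) v(t)] N² − b N

combines quadratic pair-formation births (coefficient `a`, half the average
per-pair birth probability per year), linear deaths (`b`, per year), and a
reduction of pair formation by same-sex partner choice: `p` is the
probability that an adult chooses a same-sex partner and `v(t) ≥ 0` (year⁻¹)
the selection rate scaling how strongly the complementary fraction (1 − p)
removes reproductive pairs. At p = 1 (or v ≡ 0) the classical quadratic law
is recovered.

Memory enters through the Atangana–Baleanu–Caputo (ABC) derivative

    ᴬᴮᶜD^α f(t) = B(α)/(1−α) ∫₀ᵗ f′(y) E_α(−α/(1−α)·(t−y)^α) dy,  0 < α < 1,

with the Mittag-Leffler kernel (nonsingular at y = t, fading-memory plus
power-law tails). The Riemann variant (ABR) moves the time derivative
outside the convolution. The inverse operator — the AB integral — is a
weighted average of the identity and the Riemann–Liouville fractional
integral:

    I^α f(t) = (1−α)/B(α)·f(t) + α/(B(α)Γ(α)) ∫₀ᵗ (t−y)^{α−1} f(y) dy.

**Normalization.** The literature's B(α) is only pinned at B(0) = B(1) = 1.
The default here is the common choice B(α) = 1 − α + α/Γ(α); a "unit"
variant (B ≡ 1) is selectable because published results in this model family
cannot adjudicate between them. Both appear in the same object
(`FractionalOrder`), used consistently by every operator and scheme.

**Equilibria and fate.** With v frozen at a time t, the stationary states
are N = 0 and N* = b/(a − (1−p)v). The sign of q = a − (1−p)v classifies
the long-run fate: q < 0 extinction, q = 0 (within 1e−12 absolute) critical,
q > 0 survival. Stability is deliberately *not* analyzed beyond this sign:
for the quadratic law N* is an unstable threshold (V < 0 on 0 < N < N*, so
trajectories started below N* decay toward 0 and those above blow up); the
classification refers to the existence of a positive equilibrium, and the
increment signs of computed trajectories are tested against the sign of V.

**Uniqueness.** On C[0, T] with states bounded by L, V is Lipschitz in N
with constant J = 2aL + b + 2L(1−p)·sup_{[0,T]} v. The Volterra fixed-point
map is a contraction — and the solution unique — when
(1−α)/B·J + α T^α/(B Γ(α+1))·J < 1. A "literature-strict" variant drops the
sup v factor (J = 2aL + b + 2L(1−p)), reproducing the looser constant found
in the source derivation of this bound; the default keeps sup v for
dimensional consistency. Both are reported by `uniqueness_condition`.

## Mittag-Leffler evaluation

E_{α,β}(z) = Σ z^j/Γ(αj + β) is evaluated to a caller-set absolute
tolerance (default 1e−12) by three regimes, chosen automatically from the
magnitude of the largest series term (located by ternary search on the
unimodal log-term):

* **double-precision series** when the largest term is ≤ e⁷ — cancellation
  then stays below ~1e−13;
* **asymptotic expansion** −Σ_{k≥1} z^{−k}/Γ(β − αk) for large negative z,
  truncated at the first term below 0.1·tol (accepted only if that happens
  before the terms start growing);
* **arbitrary-precision series** (mpmath) in the intermediate band, with
  working digits sized from the largest term. The gamma argument αj + β is
  formed *in working precision*: forming it in doubles leaves rounding noise
  of order eps·max-term in the alternating sum, which is catastrophic
  exactly in this band.

α = 1 with β ∈ {1, 2} short-circuits to exp/expm1. The arbiter for all
thresholds is the closed-form suite (exp, (e^z−1)/z, cosh √z, e^{x²}erfc x)
plus positivity/monotonicity of the kernel on z ≤ 0.

## Discrete operators

Functions are carried on uniform grids t_j = t0 + j·h (`SampledFunction`).

* Derivatives f′ use second-order finite differences (central inside,
  one-sided at the ends).
* The *nonsingular* kernel convolutions of ABC/ABR use the composite
  trapezoidal rule on grid nodes.
* The *weakly singular* Riemann–Liouville convolution of the AB integral
  uses product-trapezoidal weights: interpolate the data piecewise-linearly
  and integrate exactly against (t−y)^{α−1}. The weight pattern b_{j,n+1}
  (1 at the newest node; interior (n−j+2)^{α+1} + (n−j)^{α+1}
  − 2(n−j+1)^{α+1}) collapses to the composite trapezoid (1, 2, …, 2, 1) at
  α = 1 and is exact for constant *and* linear integrands — the property
  that pins the interior sign, and which the frequently mis-printed variant
  with "− (n−j)^{α+1}" fails (both facts are asserted in the tests; the
  mis-printed variant stays available as `corrected=False` precisely so the
  failure is demonstrable).

The operator identities I^α(ᴬᴮᴿD^α f) = f and I^α(ᴬᴮᶜD^α f) = f − f(0)
hold analytically; discretely they are verified to converge monotonically
under grid halving for f ∈ {t, t², sin t} on [0, 2]. The kernel behaves as
1 − λ(t−y)^α/Γ(1+α) near the diagonal, so the trapezoidal error is locally
O(h^{1+α}) rather than O(h²); convergence, not a fixed order, is the tested
contract.

## Schemes

**Predictor–corrector (`pc`).** The ABC initial-value problem is advanced
through its equivalent Volterra equation
N(t) = N(0) + I^α[V(·, N)](t). Per step:

* predictor: fractional Adams–Bashforth (rectangle weights
  (n+1−j)^α − (n−j)^α) — the scheme's source leaves the predictor
  undefined, and this is the canonical companion of the corrector;
* corrector: the product-trapezoidal (Adams–Moulton) weights above, applied
  once to the predictor value (PECE, default) or iterated to a fixed point
  (`corrector_mode="fixed-point"`, tolerance `fp_tol`); the local
  (1−α)/B·V term is treated implicitly alongside.

**Initial right limit.** The Volterra form evaluated at t → 0⁺ forces
x = N₀ + (1−α)/B·V(0, x): whenever V(0, N₀) ≠ 0 the solution *jumps* at
t = 0 — a structural feature of this operator family (its integral retains
a local term). The solver stores the datum N₀ at the first node (the
trajectory contract) but evaluates the first quadrature node at the right
limit, obtained from the scalar quadratic in closed form. Without this the
layer error never vanishes under refinement; with it the fixed-point
corrector converges at empirical order ≈ 1.2 on the linear benchmark (PECE
converges at order ≈ α, limited by the single corrector pass in the layer).

**Direct Mittag-Leffler (`direct-ml`).** The ABC derivative at the
collocation time t_{n+1} is discretized panel-by-panel with the *exact*
kernel integral ∫₀ˣ E_α(−λu^α) du = x E_{α,2}(−λx^α):

    β_{k,n} = (t_{n+1}−t_k) E_{α,2}(−λ(t_{n+1}−t_k)^α)
            − (t_{n+1}−t_{k+1}) E_{α,2}(−λ(t_{n+1}−t_{k+1})^α),  k = 0..n.

The printed source of this scheme sums over an index range that references
an unknown two steps ahead and omits the ^α inside the kernel; the form
above is the repaired version in which the unknown is N_{n+1}, every kernel
argument is non-negative, and the coefficients telescope to the full kernel
integral (the newest-panel coefficient is h·E_{α,2}(−λh^α) → h as h → 0).
Following the source's right-hand side, N_{n+1} enters the quadratic
birth/selection terms and N_n the linear death term, so each step is one
scalar quadratic solved in closed form; the root nearest N_n is taken
(continuity), with a deterministic, logged tie-break to the larger root.
Near α = 1 the scheme degenerates to a backward-Euler-like update and is
verified against a classical high-order reference.

Negative populations are never clamped — the model is defined on all reals;
they raise a log warning and are flagged in trajectory metadata. Both
schemes are deterministic: equal configuration hashes imply bitwise-equal
trajectories.

## Scenario generation and the figure suite

No empirical data exist for this model, so scenarios are synthetic by
construction. The four-member figure suite fixes α ∈ {0.95, 0.75, 0.45,
0.25} and a 100-year horizon (the only settings its source states) and uses
package-chosen survival-regime parameters a = 0.02, b = 0.01, p = 0.9,
v ≡ 0.01, N₀ = 0.1, h = 0.05 — recorded in every output's metadata as
package defaults so they cannot be mistaken for published values. The
regime generators draw a, b ∈ [0.005, 0.05] (demographically plausible
annual probabilities), p ∈ [0, 0.95], α ∈ [0.25, 0.95], and set the
constant v to place a − (1−p)v on the required side of zero (exactly zero
for "critical"), reproducibly from a seed.

What these scenarios emulate: parameter regimes spanning all three fates
and the memory-effect ordering (departure from the classical solution
growing as α decreases). What they do not: age structure, stochastic
demography, time-varying v calibrated to any census — so passing tests show
the solvers faithfully integrate *this* model, not that the model fits any
real population.

## Problem sizes and tolerances

Defaults used by the test suite and the reproduction script: figure-suite
grids h = 0.05 over 100 years (2000 steps); refinement studies on [0, 1] or
[0, 2] with 40–256 steps; equilibrium runs 100 steps. Mittag-Leffler
tolerance 1e−12; quadrature exactness asserted to 1e−12 (relative to the
integral's magnitude); equilibrium drift bound 1e−6; cross-scheme agreement
bound 5% relative sup-norm (measured ≤ 0.04%); classical-limit agreement
1e−2 relative sup-norm at α = 0.999 (measured ≈ 1.2e−3).

## Known limitations

* PECE mode resolves the t = 0⁺ layer only to first order in the corrector
  pass; use the fixed-point mode when sup-norm accuracy near t = 0 matters.
* No adaptive step-size control; the schemes are first-order-plus, so very
  stiff parameter sets need small h.
* The uniqueness bound is sufficient, not necessary — a failed contraction
  check does not imply non-uniqueness.
* The two schemes discretize slightly different formulations (Volterra vs
  derivative collocation); near strong initial layers they can legitimately
  differ at early times, which the 5% cross-scheme band accommodates.
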
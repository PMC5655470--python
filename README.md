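# fracpop

Fractional-order population dynamics with a Mittag-Leffler memory kernel.

`fracpop` is a simulator library + CLI for a nonlinear population-growth
model aimed at demographers and mathematical biologists who want to explore
how *memory effects* (fractional-order dynamics) and *partner-choice
behaviour* reshape the classical quadratic growth law.

## The model

The classical quadratic (pair-formation) law for a population density N(t) is

    dN/dt = a N² − b N

with `a` half the average per-pair birth probability per year and `b` the
average death probability per year. `fracpop` extends it in two directions:

1. **Partner choice.** With probability `p` an adult chooses a same-sex
   partner; a selection rate `v(t)` (year⁻¹) scales how strongly the
   remaining fraction reduces pair formation:

       V(t, N) = a N² − b N − (1 − p) v(t) N²

2. **Memory.** The time derivative is replaced by the
   Atangana–Baleanu–Caputo (ABC) fractional derivative of order α ∈ (0, 1],
   whose kernel is the Mittag-Leffler function
   E_α(−α/(1−α)·(t−y)^α) — nonsingular, interpolating between power-law and
   exponentially fading memory:

       ᴬᴮᶜD^α N(t) = V(t, N(t))

The equilibria are N = 0 and N* = b/(a − (1−p)v); the sign of
a − (1−p)v classifies the fate: negative → extinction, zero → critical
(delayed extinction), positive → survival. A contraction condition on the
equivalent Volterra integral equation,

    (1−α)/B(α)·J + α·T^α/(B(α)Γ(α+1))·J < 1,   J = 2aL + b + 2L(1−p)·sup v,

guarantees uniqueness of the solution on [0, T] for states bounded by L
(B(α) = 1 − α + α/Γ(α) is the operator normalization).

Two independent numerical schemes are provided:

* **`pc`** — fractional Adams–Bashforth–Moulton predictor–corrector on the
  Volterra form, with product-trapezoidal quadrature weights for the weakly
  singular kernel;
* **`direct-ml`** — direct discretization of the ABC derivative using exact
  panel integrals of the Mittag-Leffler kernel
  (∫₀ˣ E_α(−λu^α) du = x·E_{α,2}(−λx^α)); each step solves one scalar
  quadratic equation in closed form.

## Worked example

```python
from fracpop import (FractionalOrder, ModelParams, SelectionFunction,
                     SolverConfig, classify_fate, equilibria, solve_pc)

params = ModelParams(a=0.02, b=0.01, p=0.9, v=SelectionFunction.constant(0.01))
print(classify_fate(params))          # survival
print(equilibria(params).values)      # (0.0, 0.5263157894736842)

cfg = SolverConfig(h=0.05, n_steps=2000, order=FractionalOrder(0.75))
traj = solve_pc(params, 0.1, cfg)
print(round(traj.values[-1], 6))      # 0.078341
```

The fate is *survival* because a − (1−p)v = 0.02 − 0.1·0.01 = 0.019 > 0, so
a positive equilibrium N* = 0.01/0.019 ≈ 0.526 exists. Starting below it at
N₀ = 0.1 the density decays toward the extinction state (N* is unstable for
this quadratic law: V < 0 on 0 < N < N*); after 100 years at α = 0.75 the
density has fallen from 0.1 to ≈ 0.078. Smaller α (heavier memory) slows
the decay: under the same parameters the 100-year value is ≈ 0.051 at
α = 0.95 but ≈ 0.098 at α = 0.25.

Same run from the shell:

```bash
fracpop simulate --a 0.02 --b 0.01 --p 0.9 --v-const 0.01 \
    --alpha 0.75 --horizon 100 --h 0.05 --output traj.csv
fracpop figure-suite --outdir suite/        # the four-alpha suite
fracpop check-uniqueness --a 0.02 --b 0.01 --p 0.9 --v-const 0.01 \
    --bound-l 1 --horizon 1 --alpha 0.8
fracpop weights --n 10 --alpha 0.5          # corrector weight table
```

## Layout

| module | contents |
| --- | --- |
| `fracpop.mlf` | two-parameter Mittag-Leffler function E_{α,β}(z) |
| `fracpop.abcalc` | AB integral, ABC/ABR derivatives, normalization B(α) |
| `fracpop.quadrature` | product-trapezoidal weights for the singular kernel |
| `fracpop.popmodel` | V(t, N), equilibria, fate classification, uniqueness |
| `fracpop.solvers` | `solve_pc`, `solve_direct_ml`, trajectories |
| `fracpop.scenarios` | scenario configs, regime generators, figure suite |
| `fracpop.cli` | `fracpop` command-line driver |

See `docs/methods.md` for the numerical choices and their rationale.
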
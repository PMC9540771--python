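# Methods

## Model and assumptions

One host generation per season: a cohort of `ŝ` susceptibles emerges
uniformly over `[0, t_l]` and is gone by the next season. The parasite is
an obligate killer and monocyclic — it completes exactly one round of
infection per season, because hosts are only briefly susceptible after
emergence. Free parasites decay exponentially (rate `δ`); losses of free
parasites to transmission are neglected, so `v1(t) = v̂ e^{−δt}` exactly.
Infected hosts killed by background mortality (rate `μ`) release nothing;
hosts still incubating at `t = T` release nothing. Host demography is
fixed: `ŝ` does not respond to parasitism, and there is no multi-strain
resident coexistence.

## Exact within-season solution

With total susceptible hazard `h(t) = μ + Σᵢ aᵢ e^{−dᵢ t}` (one
exponential term per free-parasite population, `aᵢ = αᵢ vᵢ(0)`), the
cumulative hazard is `H(t) = μt + Σᵢ (aᵢ/dᵢ)(1 − e^{−dᵢ t})` and

    s(u) = (ŝ/t_l) ∫₀^min(u,t_l) exp(H(x) − H(u)) dx.

Because `v1(t−τ)` and the survival-to-`T` factor of released progeny are
both exponentials in `δ`, their product is constant in the release time
and the end-of-season progeny density collapses to

    v2(T) = α β e^{−μτ} v̂ e^{−δ(T−τ)} ∫₀^{T−τ} s(u) du,

valid for any `τ < T`; the two phenological regimes (`τ` below or above
`T − t_l`) differ only through the piecewise structure of `s`, so v2(T)
is continuous in `τ` across the regime boundary by construction (`τ`
exactly at the boundary needs no special-casing). For `τ ≥ T` the strain
releases nothing and `v2(T) = 0`.

The mutant fitness is the same expression with the mutant's own traits
(`αm, βm, δm, τm`, initial density `v1m(0)`) and `s` depleted by *both*
the resident pressure `α v̂* e^{−δt}` and the mutant's self-shading
pressure `αm v1m(0) e^{−δm t}`. The self-shading terms are retained even
though they are O(α) small; neutrality checks therefore use a vanishing
mutant density rather than `v1m(0) = 1`.

## Numerics

* **Emergence-phase integral.** `∫ e^{H}` is accumulated per interval
  with a 3-point Gauss–Legendre rule on 1024 uniform intervals of
  `[0, t_l]`, combined in log space (`logaddexp` accumulation), so the
  computation cannot overflow however large the trial infection pressure
  becomes during equilibrium bracketing; `s(u)` between nodes is
  propagated exactly from the nearest node plus a local Gauss–Legendre
  correction. `∫ s` uses the cubic-spline antiderivative of the node
  values on the emergence phase (error ≪ 1e−9 relative at these node
  counts) and adaptive quadrature (relative tolerance 1e−10) of the pure
  exponential-decay factor afterwards.
* **Independent oracle.** `numeric_season_oracle` integrates the
  susceptible equation with DOP853 at rtol 1e−12 (piecewise across the
  emergence discontinuity), evaluates the delayed `v2` source by lagged
  linear interpolation of the stored `s` grid, and accumulates `v2` by
  cumulative Simpson quadrature. Agreement with the analytic path is
  ~1e−10 relative at 2e5 grid points across Latin-hypercube parameter
  sets spanning the baseline magnitudes.
* **Equilibrium.** Host depletion makes the per-capita annual growth
  `v2(T; v̂)/v̂` strictly decreasing in `v̂`, so the positive fixed point
  is found by bracketed root-finding on the log growth (bracket expanded
  geometrically from the persistence threshold), to residual ~1e−12;
  plain fixed-point iteration can oscillate and is not used. If
  root-finding ever fails, a period-2 detector iterates the map and
  reports an alternating orbit rather than hiding it.
* **Selection gradient.** Central finite difference with step
  `1e−4·max(1, τ)`; within one step of the regime boundary a one-sided
  second-order stencil confined to one branch is used and flagged
  (the gradient is continuous there, the second derivative is not). The
  resident equilibrium is recomputed for every candidate resident trait,
  since the selection environment depends on it; the susceptible field
  is built once per environment and reused for all stencil points.
* **Singular strategy.** A 17-point scan of the default bracket
  `[0.05 T, 0.98 T]` (intersected with the trade-off's admissible
  interval) finds persistent residents and a sign change of the
  gradient; the root is polished by Brent's method to 1e−6 on `τ`.
  Monotone selection or universal extinction returns an explicit
  boundary diagnosis, never a fabricated root. The ESS condition is the
  sign of the central second difference (step `1e−3·max(1, τ*)`) of
  mutant fitness at fixed environment; convergence stability is the
  gradient's `+ → −` sign change across `τ*`.
* **Magnitude safety.** All hazard-dependent quantities are formed from
  the products `α ŝ` and `α v̂` (both O(1) at baseline), and exponentials
  appear only with non-positive arguments or inside log-space sums.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `ŝ` | emerging host cohort size | 1e8 | hosts |
| `t_l` | emergence period length | 1 | time |
| `T` | season length | 3 | time |
| `α` | transmission rate | 1e-8 | 1/(parasite·time) |
| `β` | progeny per killed host | 200 | parasites |
| `δ` | free-parasite decay rate | 2 | 1/time |
| `μ` | background host death rate | 0.5 | 1/time |
| `τ` | infection-to-kill delay (1/virulence) | 1.5 | time |
| `v̂` | start-of-season parasite density | 1 | parasites |

`δ` is a per-capita decay rate (1/time). `β = 200` is the package's
no-trade-off default, chosen inside the range spanned by the linear
trade-off families `99(τ + 0.5)` and `99(−τ + 4)` over the delays that
actually evolve; it is configurable everywhere. The trade-off comparison
runs at the default phenology `T = 3, t_l = 1`. Sweep grids default to
`T ∈ {2.8 … 4.0}` (anchored at 3.2 and 4.0) and
`t_l ∈ {0.01, 0.25, 0.5, 1, 1.5, 2, 2.5}` at `T = 3`. Trade-off
admissibility is clipped at `β ≥ 1` so optima cannot sit on a
zero-progeny boundary.

## Stochastic validator

The individual-based simulation emulates exactly the deterministic
assumptions at reduced scale: `n` hosts (scale factor `c = ŝ/n`, with
`α → cα` and densities `→ /c`, which preserves every per-capita hazard),
uniform emergence, exponential background death, infection by thinning
of a constant-envelope Poisson process with acceptance `e^{−δt}` (exact
for the decaying hazard `αv̂e^{−δt}`), a fixed kill delay `τ`, release of
`β` progeny when the kill precedes both background death and the season
end, and binomial survival of progeny to `T` with probability
`e^{−δ(T − release)}`. Hosts are independent under these rules, so the
deterministic model is the exact large-`n` limit and the simulated mean
equals the analytic `v2(T)` of the scaled system with no bias; the
default check uses 10 000 hosts × 50 replicates at a start density
`v̂ = 1e8` (per-host infection pressure O(1)). What the simulation does
*not* emulate: demographic feedback of parasitism on `ŝ`, depletion of
free parasites by transmission, non-exponential decay, or multi-season
stochastic competition between strains — agreement therefore validates
the season model's internal logic, not those relaxations.

## Design choices on genuinely open points

* The annual map's convergence behaviour is not guaranteed a priori;
  bracketed root-finding plus the period-2 report makes oscillatory
  dynamics visible instead of assuming a stable annual equilibrium.
* `v2m(T)` is used directly as the invasion maximand; it conditions on
  the resident-set host environment and is not a basic reproduction
  number.
* Only `τ` evolves; `α`, `β`, `δ` are fixed or tied to `τ` via the
  trade-off. No branching analysis beyond the gradient sign structure.
* The command-line `--seed` only affects the stochastic simulation;
  quadrature, equilibrium and root-finding are deterministic, so sweep
  CSVs are byte-identical across reruns.

## Problem sizes

Default runs use 1024 emergence-phase intervals, 2e5-point oracle grids
(1e6 in the sharpest cross-check), 50 Latin-hypercube parameter sets for
oracle validation, 7-point sweep grids, and 10 000-host × 50-replicate
stochastic runs; the full test suite and the reproduction script each
complete in well under a minute on one CPU.

## Known limitations

* Uniform emergence only (the emergence density enters the quadrature
  explicitly; other distributions would need a new `SusceptibleField`).
* The equilibrium solver assumes a decreasing per-capita growth; exotic
  parameter regimes violating it would surface as bracketing failures
  with diagnostics, not wrong numbers.
* `τ*` is resolved to 1e−6 absolute; orderings and offsets reported at
  coarser precision are unaffected.
* No host demographic feedback, polycyclic transmission, or non-killer
  variants; these are outside the model's scope.
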
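# phenovir

Host phenology and the evolution of virulence in seasonal obligate-killer
parasites.

## The problem

Obligate-killer parasites (parasitoids, baculoviruses, many soil-borne
pathogens) must kill their host to release infectious progeny. Classical
theory says such parasites should evolve ever-higher virulence — kill as
fast as possible — unless a mechanistic trade-off links the time to kill
with the number of progeny released. `phenovir` implements a seasonal
model in which *host phenology alone* (a bounded host activity period and
a spread of host emergence times) selects for intermediate virulence,
with no trade-off assumed.

Hosts emerge uniformly over `[0, t_l]` at the start of a season of length
`T` and live one season. Free parasites `v1` (density `v̂` at the season
start) decay at rate `δ` and infect susceptibles at rate `α`; an infected
host is killed `τ` time units after infection, releasing `β` progeny
(`v2`), unless background mortality (rate `μ`) or the season end comes
first. `τ` is the inverse of virulence. The within-season dynamics are

```
ds/dt  = ŝ g(t, t_l) − μ s − α s v1
dv1/dt = −δ v1
dv2/dt = α β e^{−μτ} s(t−τ) v1(t−τ) − δ v2
```

with `g` the uniform emergence density. Progeny left at `t = T` found the
next season, giving the annual map `v̂ → v2(T)`. The package computes:

* **exact within-season solutions** (integrating-factor quadrature) and an
  independent numerical oracle that integrates the delay system directly;
* **persistence** (`v2(T) ≥ 1` from a single founding parasite) and the
  **resident equilibrium** density `v̂*` of the annual map;
* **invasion fitness** `v2m(T)` of a rare mutant in the resident-set
  environment, the selection gradient on `τ`, and the singular strategy
  `τ*` with its ESS / convergence-stability classification;
* **trade-off variants** `β(τ)` (linear increasing or decreasing) and
  their effect on `τ*`;
* a **stochastic individual-based simulation** at reduced population
  scale that validates the deterministic model;
* **sweeps** over `T` and `t_l` reproducing the model's figure-level
  claims, from the library or the `phenovir` command line.

Intended users: theoreticians and teachers working on virulence
evolution, adaptive dynamics, or seasonal host–parasite models.

## Worked example

```python
from phenovir import (ModelParams, persistence_check, resident_equilibrium,
                      find_singular_strategy)

params = ModelParams()   # ŝ=1e8, α=1e-8, β=200, δ=2, μ=0.5, t_l=1, T=3, τ=1.5

print(persistence_check(params).growth_factor)  # 3.6417844569621316
print(resident_equilibrium(params).v_star)      # 1576689838.5306723
ss = find_singular_strategy(params)
print(ss.tau_star, ss.is_ess)                   # 1.9463154973049124 True
```

A single parasite introduced at the season start multiplies 3.64-fold
over the year, so the strain persists; iterating the annual map it
settles at about 1.58e9 free parasites per season start. Selection on
the incubation delay stops at `τ* ≈ 1.95`: the optimal strategy kills
hosts roughly one time unit before the season ends — long enough to
avoid progeny decaying in the environment, early enough that hosts are
killed before the season closes. The same computation across season
lengths shows `τ*` rising linearly with `T` at a near-constant death
offset `T − τ*`, e.g.

```bash
phenovir evolve --T 4.0        # tau_star 2.936..., offset ~1.06
phenovir sweep-T --out sweepT.csv
phenovir reproduce-all --out results/
```

`reproduce-all` writes the season-length sweep, the emergence-period
sweep and the trade-off comparison as tidy CSVs plus a manifest, and
asserts the qualitative claims (intermediate `τ*` for every `T`,
non-monotone response to emergence spread, equilibrium density falling
with emergence spread, trade-off shifts up/down for progeny-increasing/
-decreasing trade-offs).

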
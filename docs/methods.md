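# Methods

## Model

The package treats neurons as f-functional monomers undergoing random
step-growth aggregation. Assumptions: all `N` units are identical, every
one of the `f` sites on a unit is equally reactive, bonds form between
sites of distinct units with equal probability (one "extent of reaction"
`α` for the whole system), and — in the tree-like regime — no bond closes
a ring, so every bond merges two clusters. Self-bonds (two sites of one
unit) are always forbidden, in both growth modes.

Under these assumptions the crosslinking index `β = (f − 1)α` is the mean
number of link-ends per unit, and the cluster-size statistics follow the
classical Flory–Stockmayer forms, truncated for a finite system by a
generation count `k`: the weight average is built by rooting a branching
cascade at a random unit, compounding the binomial PGF
`θ(1 − α + αu)^(f−1)` through `k` generations below a root factor with
exponent `f`, and differentiating at `θ = 1`. That construction yields

    ⟨x_w⟩ = 1 + fα (1 + β + β² + … + β^k),

with the number average `⟨x_n⟩ = (1 − fα/2)⁻¹` independent of `k`. The
gel point is `β_c = 1`; a strictly ring-free finite system ends at the
spanning tree, `β_m = 2(1 − 1/N)`.

Every formula that has both a finite-f and a large-f form is exposed as a
single operation with an explicit `exact` flag (`fα` versus `β` as the
coefficient); nothing auto-switches, because at small `f` the two differ
materially (at `f = 3`, `β = 1`: `⟨x_n⟩ = 4` exact versus 2 in the limit).

## Parameters

- `N` — system size (units/neurons), integer ≥ 1. No default; the two
  built-in reference systems use 10⁴ and 10¹¹.
- `f` — functionality (connection sites per unit), integer ≥ 2 for the
  closed forms. Reference systems: 3 and 10⁴.
- `α ∈ [0, 1]`, `β = (f − 1)α ∈ [0, f − 1]` — conversion and crosslinking
  index; one determines the other at fixed `f`.
- `k` — generations of cascade compounding, integer ≥ 0. Solved from `N`
  by `k = log₂N − 2` (from `⟨x_w⟩(β_m) = N`), or `log₂((1 − e⁻²)N) − 2`
  when the monomeric fraction `e⁻²` that never joins the maximal tree is
  excluded from the reachable mass.
- Simulator defaults are desk-scale: `N = 10⁵`, `f = 100`, 20 replicates
  for acceptance-grade stochastic checks. Brain-scale values
  (`N = 10¹¹`, `f = 10⁴`) are served by the closed forms, which are
  evaluated at those sizes directly.

## Integer generation counts

Two tabulation conventions are provided by `core.table_k` because they
answer slightly different questions. For large `f` the corrected solve is
floored: `⌊log₂((1 − e⁻²)·10¹¹) − 2⌋ = 34`. For finite `f` the constraint
`1 + fα_m Σ β_m^i = N` is solved for continuous `k` with
`fα_m = 2(1 − 1/N)` and rounded to nearest: `f = 3`, `N = 10⁴` gives
24.8 → 25. Neither convention dominates; both are exposed and the CLI
labels which one each row uses implicitly through its system.

For the low-functionality pre-gel column the number average is ambiguous
between the finite form `(1 − fα/2)⁻¹ = 1.081` and the infinite-series
geometric limit `1/(1 − β) = 1.111` (the classical single-parameter
power-series convention). `ffst table1` emits both, flagged in a
`formula` column, and asserts neither as canonical. The weight average is
not ambiguous: the finite cascade form already gives 1.167 at `k = 25`.

## Numerical choices

- The geometric closed form of `⟨x_w⟩` has a removable singularity at
  `β = 1`; within 10⁻¹² of it the code dispatches to the exact limit
  `1 + fα(k + 1)`. Overflow of `β^(k+1)` raises a dedicated error rather
  than returning infinity.
- The cascade oracle differentiates the nested PGF by complex-step
  (`h = 10⁻⁴⁰`), which is cancellation-free and keeps the oracle
  independent of the geometric-sum algebra it checks. It is guarded to
  `f ≤ 10`, `k ≤ 12`: it exists to test, not to serve.
- Binomial hit probabilities go through `scipy.stats.binom` (log-space
  internally), so `n = 10⁴` does not overflow factorials. The mode set
  returns every count within 10⁻³ relative of the peak, so the
  near-degenerate twin peaks {0, 1} at `np = 1` are reported as a pair
  rather than broken arbitrarily.
- Floating comparisons in tests use relative tolerance 10⁻⁹ unless a
  printed value fixes fewer decimals; the spanning-tree reciprocal
  identity `x_n = (1 − β/2)⁻¹` is additionally checked in its exact
  integer form `N/(N − bonds)` because `1 − β/2 ≈ 1/N` loses ~`N·ε` to
  cancellation at the ceiling.

## Simulator

State is a bond ledger, per-unit free-site counts, and a union-find
partition (union by size, path halving). Bonds are drawn uniformly over
ordered pairs of free sites — equivalently, units weighted by free-site
count — which is the sampling law that reproduces `(1 − α)^f` monomer
survival. Ring-free mode rejects same-cluster draws; every accepted bond
merges two clusters, so `clusters = N − bonds` exactly and
`x_n = (1 − β/2)⁻¹` holds as an identity at every stop point and seed.

Naive rejection stalls near the spanning tree, when almost all free-site
pairs fall inside the giant cluster. After 100 consecutive same-cluster
rejections the sampler switches permanently to an exact two-pool scheme:
free sites are split into the giant cluster's pool and an "outside" pool;
a draw first picks the category — giant–outside or outside–outside —
with probability proportional to its count of *legal* pairs
(`S_g·S_m` and `(S_m² − Σ_c S_c²)/2`, maintained incrementally), then
picks sites uniformly inside the category. Pool entries invalidated by
consumption or by clusters merging into the giant are removed lazily: a
drawn entry for unit `u` is accepted with probability
`free(u)/entries(u)`, which keeps the per-unit acceptance probability
exactly proportional to its valid free sites. The fallback therefore
preserves the uniform law over legal pairs while guaranteeing
termination at `N − 1` bonds.

Rings-allowed mode accepts intra-cluster bonds (self-bonds still
rejected) and serves the post-gel regime `β > 2`, where ring formation
is unavoidable; it makes no claim to realize any particular classical
post-gel bookkeeping scheme beyond plain uniform bonding.

Replicates derive their seeds from the master seed by a fixed
golden-ratio stride (`seed + (i+1)·0x9E3779B97F4A7C15 mod 2⁶³`) feeding
Python's Mersenne Twister, so runs are bit-for-bit reproducible across
platforms.

## What the simulator does and does not emulate

It realizes exactly the combinatorial content of the theory: identical
units, equal-probability bonding, optional ring-freedom. It has no
spatial embedding, no axon/dendrite site typing, no distance-dependent
connection kernel, and no developmental time course — so agreement
between simulator and closed forms validates the statistical model's
internal consistency, not its fidelity to real cortical tissue.

Two resolution effects matter when comparing simulation to the limiting
formulas at desk scale:

- At `f = 100` the large-f limits carry relative errors of order
  `β²/2f` (monomer survival) or worse near the gel point (the weight
  average's `1/(1 − β)` amplifies the `β` versus `fα` distinction).
  These biases exceed three standard errors at `N = 10⁵` with 20
  replicates, so stochastic tests compare against the exact finite-f
  laws — `(1 − β/f)^f` and `1 + fα/(1 − (f−1)α)` — whose large-f limits
  are the familiar `e^{−β}` and `1 + β/(1 − β)`.
- A ring-free run driven to `β_m` is a spanning tree: its monomer
  fraction is identically zero, by construction. The theoretical 13.5 %
  unconnected fraction at `β = 2` describes the conversion ensemble in
  which post-gel ring formation is allowed; the simulator reproduces it
  in rings-allowed mode at `β = 2` (observed `0.1327 ± 0.0002` against
  `(1 − 0.02)¹⁰⁰ = 0.1326`).

## Known limitations

- The full cluster-size distribution `w(x)` for `x ≥ 2` is not
  implemented; only the averages, the monomer fraction and the sol/gel
  split are.
- `⟨x_w⟩(β_m = 2)` with `k = log₂N − 2` equals `2^(k+2) − 1 = N − 1`,
  not `N`; the identification with `N` is asymptotic and is tested at
  relative tolerance 10⁻⁹ for `N ≥ 2³²`.
- The redundancy bookkeeping `D = N(β − 1)` is returned (with a warning)
  for `β < 1`, where it is negative and has no loop interpretation.
- No fitting to empirical connectomes: parameters are inputs, never
  estimated.
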
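# ffst — a finite Flory–Stockmayer tree model of brain growth

`ffst` models early synaptogenesis as the step-growth aggregation of
*f*-functional monomers: each neuron carries `f` equivalent connection
sites, bonds (synapses) form between sites of distinct neurons with equal
probability, and — while growth is tree-like — no bond may close a ring.
Classical Flory–Stockmayer gelation theory, extended to a finite system of
`N` units through a k-fold compounded cascade of probability generating
functions, then gives closed forms for every headline statistic of the
growing "polyneuron" forest. The package is aimed at quantitative
neuroscientists and polymer physicists who want those statistics, and a
simulator to check them, without re-deriving anything.

With `α` the fraction of reacted sites and `β = (f − 1)α ≈ fα` the
crosslinking index (mean link-ends per neuron):

- number-average degree of polymerization `⟨x_n⟩ = (1 − fα/2)⁻¹`,
- finite-system weight average
  `⟨x_w⟩ = 1 + fα(1 + β + β² + ⋯ + β^k)`, equal to `1 + fα(k+1)` at the
  gel point `β_c = 1`,
- tree-like ceiling `β_m = 2(1 − 1/N)` (a spanning tree), where
  `⟨x_w⟩ = N` forces `N = 2^(k+2)` and hence `k = log₂N − 2`,
- monomer survival `w(1) = (1 − α)^f → e^{−β}`, sol/gel split
  `s = e^{−β}`, `g = 1 − e^{−β}` (the "brain growth" curve),
- redundancy `D = N(β − 1)` loop-forming link-ends beyond the tree
  skeleton,
- per-neuron axon-hit counts `y ~ Binomial(n, p)` with PGF
  `(1 − p + pθ)^n`, and the hardball/softball wiring radii
  `(R₂³ − R₁³)/R₁³ = (f − 2)/2`.

Four modules implement this: `ffst.core` (closed forms), `ffst.cascade`
(an independent compounded-PGF oracle, differentiated by complex step),
`ffst.simulator` (a union-find Monte-Carlo aggregation simulator with an
exact uniform-law sampler in both ring-free and ring-allowing modes), and
`ffst.synapse` (hit statistics and geometry), plus a `ffst` CLI on top.

## Worked example

The reference statistics of a low-functionality system (f = 3, N = 10⁴)
and a human-brain-scale one (f = 10⁴, N = 10¹¹), at a pre-gel state
(β = 0.1) and at the gel point (β = 1):

```text
$ ffst table1
f	N	k	beta	xn	xw	r	formula
3	10000	25	0.1	1.081	1.167	1.08	finite
3	10000	25	0.1	1.111	1.167	1.05	series_limit
3	10000	25	1.0	4	40	10	finite
10000	100000000000	34	0.1	1.053	1.111	1.06	finite
10000	100000000000	34	1.0	2	36	18	finite
```

Pre-gel clusters are tiny and nearly monodisperse (⟨x_n⟩ ≈ 1.05, r ≈ 1);
at the gel point the k = 34 generations of compounding give ⟨x_w⟩ = 36
against ⟨x_n⟩ = 2, a dispersity of 18. The `series_limit` row reports the
infinite-series candidate `x_n = 1/(1 − β)` next to the finite form for
the low-functionality pre-gel state (the two conventions differ there; see
`docs/methods.md`).

Growing an actual 10⁵-unit tree to its ceiling:

```text
$ ffst simulate --N 100000 --f 100 --target-beta 2 --ring-free --seed 1
seed=1 policy=ring_free replicates=1 mean beta_realized=1.99998
replicate	beta_realized	w1_observed	xn_observed	xw_observed	gel_fraction_observed	n_bonds
0	1.99998	0.0	100000.0	100000.0	1.0	99999
```

Ring-free growth terminates at exactly N − 1 = 99999 bonds — the spanning
tree with realized β = 2(1 − 1/N) — and a single cluster containing every
unit. Stop earlier (e.g. `--target-beta 1`) and the observed monomer
fraction, cluster averages and largest-cluster fraction track the closed
forms above; `--ring-policy rings_allowed` lifts the tree constraint for
post-gel states. `ffst growth-curve`, `ffst hit-model` and
`ffst geometry` emit the sol/gel curve, the binomial hit table
(twin modes {0, 1} at np = 1) and the wiring radii
(R₂/R₁ = (f/2)^{1/3} ≈ 17.1 at f = 10⁴).

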
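"""Monte-Carlo simulator of random bond formation among N f-functional units.

The simulator realizes the aggregation process the closed forms describe:
N units each carry f equivalent sites; bonds are drawn uniformly at random
over pairs of free sites on distinct units.  Under the ``ring_free`` policy a
draw joining two units already in the same cluster is rejected, so growth is
strictly tree-like and terminates at the spanning tree (N - 1 bonds, mean
degree 2*(1 - 1/N)).  Under ``rings_allowed`` intra-cluster bonds are
accepted; only self-bonds (two sites on one unit) are ever forbidden.

Naive rejection stalls near tree saturation, when almost every random pair
falls inside the giant cluster.  After 100 consecutive same-cluster
rejections the sampler switches to an exact two-pool scheme that draws
uniformly among the *legal* inter-cluster free-site pairs (giant-outside and
outside-outside categories, weighted by their pair counts, with lazy
invalidation of stale pool entries), preserving the uniform law while
guaranteeing termination.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ConfigError

__all__ = [
    "RING_FREE",
    "RINGS_ALLOWED",
    "SimConfig",
    "SimState",
    "SimSummary",
    "ReplicateSet",
    "init_system",
    "grow",
    "summarize",
    "run_replicates",
    "replicate_seed",
]

RING_FREE = "ring_free"
RINGS_ALLOWED = "rings_allowed"

_FALLBACK_AFTER = 100  # consecutive same-cluster rejections before pool switch


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one aggregation run.

    ``target_beta`` is the stop condition expressed as mean degree
    (2 * bonds / N).  Under ``ring_free`` it may not exceed the tree-like
    ceiling 2; realized beta saturates at 2*(1 - 1/N), the spanning tree.
    Under ``rings_allowed`` it may not exceed the site capacity f.
    """

    N: int
    f: int
    target_beta: float
    ring_policy: str = RING_FREE
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigError(f"N must be >= 2, got {self.N}")
        if self.f < 1:
            raise ConfigError(f"f must be >= 1, got {self.f}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if self.ring_policy not in (RING_FREE, RINGS_ALLOWED):
            raise ConfigError(f"unknown ring_policy {self.ring_policy!r}")
        if self.target_beta < 0:
            raise ConfigError(f"target_beta must be >= 0, got {self.target_beta}")
        if self.ring_policy == RING_FREE and self.target_beta > 2.0 + 1e-12:
            raise ConfigError(
                f"target_beta={self.target_beta} exceeds the tree-like ceiling 2 "
                f"(realized beta saturates at 2*(1-1/N)={2 * (1 - 1 / self.N)})"
            )
        if self.ring_policy == RINGS_ALLOWED and self.target_beta > self.f + 1e-12:
            raise ConfigError(
                f"target_beta={self.target_beta} exceeds the site capacity f={self.f}"
            )


class DisjointSets:
    """Union-find partition with union by size and path halving."""

    __slots__ = ("parent", "size", "count")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.count = n

    def find(self, x: int) -> int:
        parent = self.parent
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union_roots(self, a: int, b: int) -> int:
        """Merge two distinct roots; returns the surviving root."""
        if self.size[a] < self.size[b]:
            a, b = b, a
        self.parent[b] = a
        self.size[a] += self.size[b]
        self.count -= 1
        return a

    def cluster_sizes(self) -> List[int]:
        sizes = []
        for u in range(len(self.parent)):
            if self.find(u) == u:
                sizes.append(self.size[u])
        return sizes


class SimState:
    """Mutable state of one run: bond ledger, free sites, cluster partition."""

    def __init__(self, config: SimConfig) -> None:
        self.config = config
        N, f = config.N, config.f
        self.bonds: List[Tuple[int, int]] = []
        self.free_sites: List[int] = [f] * N
        self.partition = DisjointSets(N)
        self._rng = random.Random(config.seed)
        # one pool entry per free site, labelled by its owner unit
        self._pool: List[int] = [u for u in range(N) for _ in range(f)]
        self._free_total = N * f
        self._units_with_free = N
        # per-root free-site counts, for termination checks and the fallback
        self._cluster_free: Dict[int, int] = {u: f for u in range(N)}
        # fallback-mode structures (built on demand)
        self._fallback = False
        self._giant = -1
        self._outside: List[int] = []
        self._pool_entries: List[int] = []
        self._outside_entries: List[int] = []
        self._S_m = 0  # free sites outside the giant cluster
        self._sum_sq = 0.0  # sum of squared per-cluster free counts, outside

    # -- observables -----------------------------------------------------

    @property
    def N(self) -> int:
        return self.config.N

    @property
    def beta_realized(self) -> float:
        return 2.0 * len(self.bonds) / self.config.N

    # -- site pools ------------------------------------------------------

    def _pop_pool(self, i: int) -> None:
        pool = self._pool
        pool[i] = pool[-1]
        pool.pop()

    def _pop_outside(self, i: int) -> None:
        out = self._outside
        out[i] = out[-1]
        out.pop()

    # -- naive sampling (exact pool) -------------------------------------

    def _draw_naive(self):
        """Uniform draw over free-site pairs with rejection; exact pool."""
        rng = self._rng
        pool = self._pool
        ring_free = self.config.ring_policy == RING_FREE
        find = self.partition.find
        consecutive = 0
        while True:
            if ring_free:
                if self.partition.count == 1 or len(self._cluster_free) < 2:
                    return None
            elif self._units_with_free < 2:
                return None
            n = len(pool)
            i = rng.randrange(n)
            j = rng.randrange(n)
            if i == j:
                continue
            u, v = pool[i], pool[j]
            if u == v:
                continue  # self-bond: always forbidden
            if ring_free:
                ru, rv = find(u), find(v)
                if ru == rv:
                    consecutive += 1
                    if consecutive >= _FALLBACK_AFTER:
                        self._enter_fallback()
                        return self._draw_fallback()
                    continue
            else:
                ru, rv = find(u), find(v)
            if i < j:
                i, j = j, i
            self._pop_pool(i)
            self._pop_pool(j)
            return u, v, ru, rv

    # -- fallback sampling (legal-pair categories) ------------------------

    def _enter_fallback(self) -> None:
        N = self.config.N
        find = self.partition.find
        size = self.partition.size
        giant = max((find(u) for u in range(N)), key=lambda r: size[r])
        self._giant = giant
        free = self.free_sites
        outside: List[int] = []
        outside_entries = [0] * N
        for u in range(N):
            fu = free[u]
            if fu and find(u) != giant:
                outside.extend([u] * fu)
                outside_entries[u] = fu
        self._outside = outside
        self._outside_entries = outside_entries
        self._pool_entries = list(free)  # the naive pool is exact at switch
        self._S_m = len(outside)
        self._sum_sq = float(
            sum(c * c for r, c in self._cluster_free.items() if r != giant)
        )
        self._fallback = True

    def _draw_site_validated(
        self, sites: List[int], entries: List[int], want_giant: bool
    ) -> int:
        """Index of a uniformly chosen *valid* free site in one pool.

        Pools may hold stale entries (consumed sites, or units that migrated
        into/out of the giant).  A drawn entry for unit u is accepted with
        probability free[u]/entries[u] when u belongs to the wanted side
        (0 otherwise), which makes the acceptance probability of u exactly
        proportional to its valid free sites; rejected entries are removed.
        """
        rng = self._rng
        free = self.free_sites
        find = self.partition.find
        giant = self._giant
        while True:
            i = rng.randrange(len(sites))
            u = sites[i]
            in_giant = find(u) == giant
            target = free[u] if in_giant == want_giant else 0
            e = entries[u]
            if target >= e or (target > 0 and rng.random() < target / e):
                return i
            # stale entry: drop it and redraw
            entries[u] -= 1
            sites[i] = sites[-1]
            sites.pop()

    def _draw_fallback(self):
        """Uniform draw over legal inter-cluster pairs via category weights."""
        rng = self._rng
        find = self.partition.find
        while True:
            if self.partition.count == 1 or self._S_m == 0:
                return None
            s_g = self._free_total - self._S_m
            s_m = self._S_m
            w_cross = float(s_g) * s_m
            w_outside = (float(s_m) * s_m - self._sum_sq) / 2.0
            total = w_cross + w_outside
            if total <= 0:
                return None
            if rng.random() * total < w_cross:
                i = self._draw_site_validated(self._pool, self._pool_entries, True)
                u = self._pool[i]
                j = self._draw_site_validated(self._outside, self._outside_entries, False)
                v = self._outside[j]
                ru, rv = find(u), find(v)
                self._pool[i] = self._pool[-1]
                self._pool.pop()
                self._pool_entries[u] -= 1
                self._consume_outside(j, v)
                return u, v, ru, rv
            # outside-outside: rejection within the category is cheap because
            # the category weight is already proportional to its legal pairs
            while True:
                i = self._draw_site_validated(self._outside, self._outside_entries, False)
                j = self._draw_site_validated(self._outside, self._outside_entries, False)
                if i == j:
                    continue
                u, v = self._outside[i], self._outside[j]
                if u == v:
                    continue
                ru, rv = find(u), find(v)
                if ru == rv:
                    break  # same cluster: re-enter the outer category draw
                if i < j:
                    i, j = j, i
                self._consume_outside(i, self._outside[i])
                self._consume_outside(j, self._outside[j])
                return u, v, ru, rv

    def _consume_outside(self, i: int, u: int) -> None:
        self._pop_outside(i)
        self._outside_entries[u] -= 1
        self._S_m -= 1
        root = self.partition.find(u)
        c = self._cluster_free[root]
        self._sum_sq += (c - 1) ** 2 - c * c
        self._cluster_free[root] = c - 1

    # -- bond application -------------------------------------------------

    def _apply_bond(self, u: int, v: int, ru: int, rv: int) -> None:
        self.bonds.append((u, v))
        free = self.free_sites
        for w in (u, v):
            free[w] -= 1
            if free[w] == 0:
                self._units_with_free -= 1
        self._free_total -= 2
        ring_free = self.config.ring_policy == RING_FREE
        if not ring_free:
            if ru != rv:
                self.partition.union_roots(ru, rv)
            return
        # ring-free: every bond merges two clusters
        cf = self._cluster_free
        if self._fallback:
            giant = self._giant
            fa = cf.pop(ru)
            fb = cf.pop(rv)
            if ru == giant or rv == giant:
                # the outside cluster is absorbed: its remaining free sites
                # leave the outside pool (entries invalidated lazily); the
                # outside endpoint's own consumed site was already booked
                other_free = fb if ru == giant else fa
                self._S_m -= other_free
                self._sum_sq -= other_free * other_free
                # outside endpoint's site was booked in _consume_outside, so
                # only the giant's consumed site is subtracted here
                merged = fa + fb - 1
                root = self.partition.union_roots(ru, rv)
                self._giant = root
            else:
                merged = fa + fb
                self._sum_sq += merged * merged - fa * fa - fb * fb
                root = self.partition.union_roots(ru, rv)
            if merged > 0:
                cf[root] = merged
        else:
            fa = cf.pop(ru)
            fb = cf.pop(rv)
            merged = fa + fb - 2
            root = self.partition.union_roots(ru, rv)
            if merged > 0:
                cf[root] = merged

    # -- growth ------------------------------------------------------------

    def step(self) -> bool:
        """Attempt one bond; returns False when no legal bond exists."""
        drawn = self._draw_fallback() if self._fallback else self._draw_naive()
        if drawn is None:
            return False
        self._apply_bond(*drawn)
        return True


def init_system(config: SimConfig) -> SimState:
    """Fresh state: N singleton clusters, zero bonds, all f sites free."""
    return SimState(config)


def grow(
    state: SimState, config: Optional[SimConfig] = None, target_beta: Optional[float] = None
) -> SimState:
    """Grow until realized beta reaches the target or no legal bond remains.

    ``target_beta`` overrides the configured stop condition, which allows
    resuming a run at successively larger targets (growth snapshots).
    """
    cfg = state.config if config is None else config
    tb = cfg.target_beta if target_beta is None else target_beta
    if tb > cfg.target_beta:
        # re-validate the raised target against the policy bounds
        replace(cfg, target_beta=tb)
    bonds_needed = math.ceil(tb * cfg.N / 2.0 - 1e-9)
    while len(state.bonds) < bonds_needed:
        if not state.step():
            break
    return state


@dataclass(frozen=True)
class SimSummary:
    """Observed statistics of one run (or an aggregate of runs)."""

    N: int
    n_bonds: int
    beta_realized: float
    w1_observed: float
    xn_observed: float
    xw_observed: float
    gel_fraction_observed: float
    cluster_size_histogram: Dict[int, int] = field(default_factory=dict)

    OBSERVABLES = (
        "beta_realized",
        "w1_observed",
        "xn_observed",
        "xw_observed",
        "gel_fraction_observed",
    )


def summarize(state: SimState) -> SimSummary:
    """Compute the observables the closed forms predict.

    xn = N / #clusters, xw = sum(size^2) / N, w1 = fraction of units with no
    bond, gel fraction = largest-cluster weight fraction (the standard
    percolation estimator of the giant component).
    """
    N, f = state.config.N, state.config.f
    sizes = state.partition.cluster_sizes()
    hist: Dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    n_free = sum(1 for c in state.free_sites if c == f)
    return SimSummary(
        N=N,
        n_bonds=len(state.bonds),
        beta_realized=state.beta_realized,
        w1_observed=n_free / N,
        xn_observed=N / len(sizes),
        xw_observed=sum(s * s for s in sizes) / N,
        gel_fraction_observed=max(sizes) / N,
        cluster_size_histogram=hist,
    )


def replicate_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: golden-ratio stride from the master."""
    return (master_seed + (index + 1) * 0x9E3779B97F4A7C15) % 2**63


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate summaries with per-observable mean and standard error."""

    config: SimConfig
    summaries: Tuple[SimSummary, ...]
    mean: Dict[str, float]
    se: Dict[str, float]


def _mean_se(values: Sequence[float]) -> Tuple[float, float]:
    n = len(values)
    m = sum(values) / n
    if n == 1:
        return m, 0.0
    var = sum((v - m) ** 2 for v in values) / (n - 1)
    return m, math.sqrt(var / n)


def run_replicates(config: SimConfig) -> ReplicateSet:
    """Independent replicates with seeds derived from the master seed.

    Bit-for-bit reproducible for a fixed master seed: replicate ``i`` runs
    with :func:`replicate_seed(config.seed, i)`.
    """
    summaries = []
    for i in range(config.replicates):
        cfg_i = replace(config, seed=replicate_seed(config.seed, i), replicates=1)
        state = grow(init_system(cfg_i))
        summaries.append(summarize(state))
    mean: Dict[str, float] = {}
    se: Dict[str, float] = {}
    for name in SimSummary.OBSERVABLES:
        mean[name], se[name] = _mean_se([getattr(s, name) for s in summaries])
    return ReplicateSet(config=config, summaries=tuple(summaries), mean=mean, se=se)
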
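"""Per-neuron synapse statistics: binomial axon-hit model and wiring geometry.

An incoming axon sees a target neuron as ``n`` available postsynaptic sites,
each hit independently with probability ``p``; the hit count ``y`` is
binomial with PGF ``phi(theta) = (1 - p + p*theta)**n`` and mean ``n*p``.
Since ``n`` is a large constant and ``p`` small, the distribution sits in
the Poisson regime: at ``n*p = 1`` it shows near-equal twin peaks at 0 and 1
hits, and the no-hit probability tracks ``exp(-n*p)``.

The wiring geometry splits a neuron's reach into a rigid inner "hardball"
(radius R1, carrying exactly the 2 tree-skeleton twin synapses) and a
flexible outer "softball" shell (radius R2) holding the remaining f - 2
loop-forming contacts.  Uniform synapse density gives
``(R2**3 - R1**3) / R1**3 = (f - 2) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Set, Union

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "hit_pmf",
    "hit_pgf",
    "hit_mean",
    "hit_profile",
    "softball_radius_ratio",
    "HitModel",
    "BallGeometry",
]

ArrayLike = Union[int, float, np.ndarray]


def _check_np(n: int, p: float) -> None:
    if n < 0 or int(n) != n:
        raise DomainError(f"site count n must be a nonnegative integer, got {n}")
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"hit probability p must lie in [0, 1], got {p}")


def hit_pmf(y: ArrayLike, n: int, p: float) -> ArrayLike:
    """Binomial probability of exactly y hits on n sites (log-space safe)."""
    _check_np(n, p)
    y_arr = np.asarray(y)
    if np.any(y_arr < 0) or np.any(y_arr > n) or not np.all(np.equal(np.mod(y_arr, 1), 0)):
        raise DomainError(f"hit count y must be an integer in [0, {n}]")
    out = stats.binom.pmf(y_arr, n, p)
    return float(out) if np.isscalar(y) or y_arr.ndim == 0 else out


def hit_pgf(theta: ArrayLike, n: int, p: float) -> ArrayLike:
    """PGF ``(1 - p + p*theta)**n`` of the hit count."""
    _check_np(n, p)
    t = np.asarray(theta, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise DomainError("PGF dummy variable theta must lie in [0, 1]")
    out = (1.0 - p + p * t) ** n
    return float(out) if np.isscalar(theta) else out


def hit_mean(n: int, p: float) -> float:
    """Analytic derivative of the PGF at theta = 1: the mean hit count n*p."""
    _check_np(n, p)
    return n * p


def hit_profile(n: int, p: float, rel_tol: float = 1e-3) -> Set[int]:
    """Most probable hit counts: the argmax set of the pmf.

    Counts whose probability is within ``rel_tol`` (relative) of the maximum
    are all returned, so the near-degenerate Poisson-regime twin peaks at
    ``n*p = 1`` come back as {0, 1} rather than an arbitrary tie-break.
    """
    _check_np(n, p)
    if p == 0.0:
        return {0}
    if p == 1.0:
        return {n}
    mean = n * p
    sd = math.sqrt(n * p * (1.0 - p))
    lo = max(0, math.floor(mean - 10.0 * sd - 10.0))
    hi = min(n, math.ceil(mean + 10.0 * sd + 10.0))
    ys = np.arange(lo, hi + 1)
    pmf = stats.binom.pmf(ys, n, p)
    peak = pmf.max()
    return {int(y) for y, q in zip(ys, pmf) if q >= peak * (1.0 - rel_tol)}


def softball_radius_ratio(f: int) -> float:
    """Softball/hardball radius ratio ``(f/2)**(1/3)``.

    From uniform synapse density with 2 synapses inside the hardball and
    f - 2 in the shell: ``(R2^3 - R1^3)/R1^3 = (f-2)/2``, i.e.
    ``R2/R1 = (1 + (f-2)/2)**(1/3) = (f/2)**(1/3)``.
    """
    if f < 2:
        raise DomainError(f"functionality f must be >= 2, got {f}")
    return (f / 2.0) ** (1.0 / 3.0)


@dataclass(frozen=True)
class HitModel:
    """Binomial hit model bound to one (n, p) pair."""

    n: int
    p: float

    def __post_init__(self) -> None:
        _check_np(self.n, self.p)

    @property
    def mean(self) -> float:
        return hit_mean(self.n, self.p)

    def pmf(self, y: ArrayLike) -> ArrayLike:
        return hit_pmf(y, self.n, self.p)

    def pgf(self, theta: ArrayLike) -> ArrayLike:
        return hit_pgf(theta, self.n, self.p)

    def modes(self, rel_tol: float = 1e-3) -> Set[int]:
        return hit_profile(self.n, self.p, rel_tol)

    def pmf_table(self, y_max: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(y, probability) arrays covering the bulk of the distribution."""
        if y_max is None:
            sd = math.sqrt(self.n * self.p * (1.0 - self.p))
            y_max = min(self.n, math.ceil(self.n * self.p + 10.0 * sd + 10.0))
        ys = np.arange(0, y_max + 1)
        return ys, stats.binom.pmf(ys, self.n, self.p)


@dataclass(frozen=True)
class BallGeometry:
    """Hardball/softball radii of an f-functional neuron (R1 sets the unit)."""

    f: int
    R1: float = 1.0
    hardball_synapses: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        if self.f < 2:
            raise DomainError(f"functionality f must be >= 2, got {self.f}")
        if self.R1 <= 0:
            raise DomainError(f"hardball radius R1 must be positive, got {self.R1}")

    @property
    def R2(self) -> float:
        return self.R1 * softball_radius_ratio(self.f)

    @property
    def softball_synapses(self) -> int:
        return self.f - self.hardball_synapses
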
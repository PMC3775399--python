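"""Parameter bundles and result records for the finite Flory-Stockmayer tree model.

The model views neurons as f-functional monomers: each unit carries ``f``
equivalent connection sites, a fraction ``alpha`` of all sites has reacted
(formed synapses), and the crosslinking index ``beta = (f - 1) * alpha`` is
the mean number of link-ends per unit.  The gel point sits at ``beta_c = 1``
and a strictly tree-like (ring-free) system cannot exceed
``beta_m = 2 * (1 - 1/N)``, the mean degree of a spanning tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ConsistencyError, DomainError

#: Crosslinking index at the gel point (emergence of the giant cluster).
BETA_C: float = 1.0

#: Large-system tree-like ceiling of the crosslinking index.
BETA_M_LIMIT: float = 2.0

_REL_TOL = 1e-9


def beta_from_alpha(alpha: float, f: int) -> float:
    """Crosslinking index ``beta = (f - 1) * alpha``."""
    return (f - 1) * alpha


def alpha_from_beta(beta: float, f: int) -> float:
    """Extent of reaction implied by ``beta`` at finite functionality."""
    if f < 2:
        raise DomainError(f"functionality f must be >= 2 to invert beta, got {f}")
    return beta / (f - 1)


@dataclass
class FFSTParams:
    """Parameter bundle: system size, functionality, conversion and bounds.

    Exactly one of ``alpha``/``beta`` may be given; the other is derived via
    ``beta = (f - 1) * alpha``.  If both are given they must agree.
    """

    N: Optional[int] = None
    f: Optional[int] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    k: Optional[int] = None

    beta_c: float = BETA_C

    def __post_init__(self) -> None:
        if self.N is not None and self.N < 1:
            raise DomainError(f"system size N must be >= 1, got {self.N}")
        if self.f is not None and self.f < 2:
            raise DomainError(f"functionality f must be >= 2, got {self.f}")
        if self.k is not None and self.k < 0:
            raise DomainError(f"generation count k must be >= 0, got {self.k}")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise DomainError(f"extent of reaction alpha must lie in [0, 1], got {self.alpha}")
        if self.alpha is not None and self.beta is not None and self.f is not None:
            expected = beta_from_alpha(self.alpha, self.f)
            if not math.isclose(self.beta, expected, rel_tol=_REL_TOL, abs_tol=_REL_TOL):
                raise ConsistencyError(
                    f"beta={self.beta} inconsistent with (f-1)*alpha={expected}"
                )
        elif self.alpha is not None and self.beta is None and self.f is not None:
            self.beta = beta_from_alpha(self.alpha, self.f)
        elif self.beta is not None and self.alpha is None and self.f is not None:
            self.alpha = alpha_from_beta(self.beta, self.f)
        if self.beta is not None:
            if self.beta < 0:
                raise DomainError(f"beta must be >= 0, got {self.beta}")
            if self.f is not None and self.beta > self.f - 1 + _REL_TOL:
                raise DomainError(f"beta={self.beta} exceeds its ceiling f-1={self.f - 1}")

    @property
    def beta_m(self) -> float:
        """Maximum tree-like beta: ``2(1 - 1/N)``, or the large-N limit 2."""
        if self.N is None:
            return BETA_M_LIMIT
        return 2.0 * (1.0 - 1.0 / self.N)


@dataclass(frozen=True)
class DPAverages:
    """Number- and weight-average degrees of polymerization and dispersity."""

    xn: float
    xw: float

    def __post_init__(self) -> None:
        if self.xn <= 0:
            raise DomainError(f"number-average DP must be positive, got {self.xn}")

    @property
    def r(self) -> float:
        """Dispersity, the ratio of weight- to number-average DP."""
        return self.xw / self.xn


@dataclass(frozen=True)
class RedundancyResult:
    """Linkage bookkeeping: total link-ends N*beta and redundancy N*(beta-1)."""

    total_linkages: float
    D: float


@dataclass
class SolGelState:
    """Sol/gel split of a post-gel system.

    ``s`` and ``g`` are weight fractions of the finite (sol) and giant (gel)
    phases; ``w1`` the monomer weight fraction; primed quantities are
    per-phase averages.  Conservation requires ``s + g = 1`` and, where the
    per-phase crosslinking indices are known, ``beta = s*beta_sol + g*beta_gel``.
    """

    s: float
    g: float
    w1: Optional[float] = None
    beta_sol: Optional[float] = None
    beta_gel: Optional[float] = None
    xn_sol: Optional[float] = None
    xw_sol: Optional[float] = None
    xn_gel: Optional[float] = None
    xw_gel: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("s", "g"):
            v = getattr(self, name)
            if not -_REL_TOL <= v <= 1.0 + _REL_TOL:
                raise DomainError(f"{name}={v} is not a weight fraction in [0, 1]")
        if abs(self.s + self.g - 1.0) > 1e-9:
            raise ConsistencyError(f"sol + gel fractions must sum to 1, got {self.s + self.g}")
        if self.w1 is not None and self.w1 > self.s + 1e-9:
            raise ConsistencyError(
                f"monomer fraction w1={self.w1} exceeds sol fraction s={self.s}"
            )

    @property
    def beta(self) -> Optional[float]:
        """System beta recovered from the phase mixture, if both phases are set."""
        if self.beta_sol is None or self.beta_gel is None:
            return None
        return self.s * self.beta_sol + self.g * self.beta_gel
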
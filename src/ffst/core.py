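"""Closed-form statistics of finite Flory-Stockmayer (tree-like) aggregation.

All operations work on the crosslinking index ``beta = (f - 1) * alpha``
(mean link-ends per unit).  Each formula that has both a finite-f and a
large-f limiting form takes an explicit ``exact`` flag; nothing is
auto-switched.  In exact mode the coefficient is ``f * alpha`` with
``alpha = beta / (f - 1)``; in the large-f limit ``f * alpha -> beta``.

Key quantities
--------------
number-average DP   xn = 1 / (1 - f*alpha/2)
weight-average DP   xw = 1 + f*alpha * (1 + beta + ... + beta**k)
gel point           beta_c = 1, where xw(beta_c) = 1 + f*alpha*(k + 1)
tree ceiling        beta_m = 2 * (1 - 1/N)
monomer fraction    w1 = (1 - alpha)**f  ->  exp(-beta)
gel fraction        g = 1 - exp(-beta)
redundancy          D = N * (beta - 1) loop-forming link-ends beyond the tree
"""

from __future__ import annotations

import math
import warnings
from types import SimpleNamespace
from typing import Optional

from .errors import ConsistencyError, DomainError, GelOverflowError, SingularityError
from .params import DPAverages, RedundancyResult

__all__ = [
    "number_avg_dp",
    "weight_avg_dp",
    "dispersity",
    "dp_averages",
    "solve_generations",
    "solve_generations_finite",
    "table_k",
    "beta_max",
    "monomer_weight_fraction",
    "sol_fraction",
    "gel_fraction",
    "sol_gel_mix",
    "gel_phase_beta",
    "redundancy",
]

_BETA_ONE_TOL = 1e-12
_GM = 1.0 - math.exp(-2.0)  # gel fraction at the tree ceiling beta_m = 2


def _coefficient(beta: float, f: Optional[int], exact: bool) -> float:
    """Return f*alpha for the requested mode, validating the domain."""
    if beta < 0:
        raise DomainError(f"beta must be >= 0, got {beta}")
    if not exact:
        return beta
    if f is None or f < 2:
        raise DomainError(f"exact mode requires finite functionality f >= 2, got {f}")
    alpha = beta / (f - 1)
    if alpha > 1.0 + 1e-12:
        raise DomainError(f"beta={beta} implies alpha={alpha} > 1 at f={f}")
    return f * alpha


def number_avg_dp(beta: float, f: Optional[int] = None, *, exact: bool = False) -> float:
    """Number-average degree of polymerization ``1 / (1 - f*alpha/2)``.

    Diverges as ``f*alpha -> 2`` (equivalently ``beta -> 2`` in the large-f
    limit): in a finite system the pole is cut off at the spanning-tree
    ceiling ``beta_m = 2 * (1 - 1/N)``.
    """
    fa = _coefficient(beta, f, exact)
    if fa >= 2.0:
        raise SingularityError(
            f"f*alpha={fa} >= 2: the number average diverges at the tree ceiling "
            "beta_m = 2*(1 - 1/N) (large-N limit 2)"
        )
    return 1.0 / (1.0 - fa / 2.0)


def weight_avg_dp(
    beta: float, k: int, f: Optional[int] = None, *, exact: bool = False
) -> float:
    """Finite-system weight-average DP ``1 + f*alpha * sum(beta**i, i=0..k)``.

    ``k`` is the number of generations of compounding in the cascade
    (branching-process) construction.  The geometric closed form
    ``1 + f*alpha * (1 - beta**(k+1)) / (1 - beta)`` has a removable
    singularity at the gel point; within ``1e-12`` of ``beta = 1`` the exact
    limit ``1 + f*alpha * (k + 1)`` is used instead.
    """
    if k < 0 or int(k) != k:
        raise DomainError(f"generation count k must be a nonnegative integer, got {k}")
    fa = _coefficient(beta, f, exact)
    if abs(beta - 1.0) < _BETA_ONE_TOL:
        return 1.0 + fa * (k + 1)
    try:
        bk = beta ** (k + 1)
    except OverflowError as exc:
        raise GelOverflowError(f"beta**(k+1) overflows for beta={beta}, k={k}") from exc
    if math.isinf(bk):
        raise GelOverflowError(f"beta**(k+1) overflows for beta={beta}, k={k}")
    return 1.0 + fa * (1.0 - bk) / (1.0 - beta)


def dispersity(xn: float, xw: float) -> float:
    """Dispersity ``r = xw / xn`` (1 for a monodisperse system)."""
    if xn <= 0:
        raise DomainError(f"number-average DP must be positive, got {xn}")
    return xw / xn


def dp_averages(
    beta: float, k: int, f: Optional[int] = None, *, exact: bool = False
) -> DPAverages:
    """Both DP averages at the same state, bundled with their dispersity."""
    return DPAverages(
        xn=number_avg_dp(beta, f, exact=exact),
        xw=weight_avg_dp(beta, k, f, exact=exact),
    )


def solve_generations(N: float, *, corrected: bool = False) -> float:
    """Continuous generation count from the system-size constraint.

    At the tree ceiling the weight average exhausts the system, giving
    ``N = 2**(k+2)`` and hence ``k = log2(N) - 2``.  The corrected variant
    replaces N by the tree-reachable mass ``(1 - exp(-2)) * N``, since a
    fraction ``exp(-2)`` of units stays monomeric at ``beta_m``.
    """
    if N < 4:
        raise DomainError(f"system size N must be >= 4 so that k >= 0, got {N}")
    eff = _GM * N if corrected else float(N)
    k = math.log2(eff) - 2.0
    if k < 0:
        raise DomainError(f"corrected solve gives negative k for N={N}")
    return k


def solve_generations_finite(N: float, f: int) -> float:
    """Continuous k solving ``1 + f*alpha_m * sum(beta_m**i, i=0..k) = N``.

    Finite-functionality counterpart of :func:`solve_generations`: the
    maximum conversion is fixed by ``f*alpha_m = 2*(1 - 1/N)`` and the sum
    runs in ``beta_m = (f - 1) * alpha_m``.
    """
    if N < 2:
        raise DomainError(f"system size N must be >= 2, got {N}")
    if f < 2:
        raise DomainError(f"functionality f must be >= 2, got {f}")
    fam = 2.0 * (1.0 - 1.0 / N)
    beta_m = (f - 1) * fam / f
    if beta_m <= 1.0:
        raise DomainError(f"finite-f solve needs beta_m > 1, got {beta_m} (f={f}, N={N})")
    target = (N - 1.0) / fam  # sum of the geometric series
    return math.log1p(target * (beta_m - 1.0)) / math.log(beta_m) - 1.0


def table_k(N: float, f: Optional[int] = None) -> int:
    """Integer generation count under the tabulation conventions.

    Large-f (``f=None``): floor of the corrected continuous solve.
    Finite f: nearest integer to the finite-functionality solve.  The two
    conventions are deliberately distinct; see the methods note.
    """
    if f is None:
        return math.floor(solve_generations(N, corrected=True))
    return round(solve_generations_finite(N, f))


def beta_max(N: float) -> float:
    """Spanning-tree ceiling ``beta_m = 2 * (1 - 1/N)``; tends to 2 as N grows."""
    if N < 1:
        raise DomainError(f"system size N must be >= 1, got {N}")
    return 2.0 * (1.0 - 1.0 / N)


def monomer_weight_fraction(
    alpha: Optional[float] = None,
    f: Optional[int] = None,
    *,
    beta: Optional[float] = None,
    limit: bool = False,
) -> float:
    """Weight fraction of unconnected monomers.

    Exact: ``(1 - alpha)**f`` (the probability that all f sites are unreacted).
    Large-f limit (``limit=True``): ``exp(-beta)``, taking beta directly or
    deriving it from ``(f - 1) * alpha``.
    """
    if limit:
        if beta is None:
            if alpha is None or f is None:
                raise DomainError("limit mode needs beta, or alpha together with f")
            beta = (f - 1) * alpha
        if beta < 0:
            raise DomainError(f"beta must be >= 0, got {beta}")
        return math.exp(-beta)
    if alpha is None or f is None:
        raise DomainError("exact mode needs both alpha and f")
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    return (1.0 - alpha) ** f


def sol_fraction(beta: float) -> float:
    """Post-gel sol weight fraction ``s = exp(-beta)`` (monomer-dominated)."""
    if beta < 0:
        raise DomainError(f"beta must be >= 0, got {beta}")
    return math.exp(-beta)


def gel_fraction(beta: float) -> float:
    """Gel (giant-cluster) weight fraction ``g = 1 - exp(-beta)``."""
    return 1.0 - sol_fraction(beta)


def sol_gel_mix(
    s: float,
    g: float,
    *,
    xn_sol: Optional[float] = None,
    xn_gel: Optional[float] = None,
    xw_sol: Optional[float] = None,
    xw_gel: Optional[float] = None,
    beta_sol: Optional[float] = None,
    beta_gel: Optional[float] = None,
    tol: float = 1e-9,
) -> SimpleNamespace:
    """Combine per-phase averages into system-level averages.

    The number average mixes harmonically (``1/xn = s/xn' + g/xn''``: molecule
    counts add), while the weight average and the crosslinking index mix
    arithmetically (``xw = s*xw' + g*xw''``, ``beta = s*beta' + g*beta''``:
    mass-weighted means add).  Returns a namespace with whichever of
    ``xn``, ``xw``, ``beta`` could be formed (others are None).
    """
    if abs(s + g - 1.0) > tol:
        raise ConsistencyError(f"sol + gel fractions must sum to 1, got {s + g}")
    xn = xw = beta = None
    if xn_sol is not None and xn_gel is not None:
        if (s > 0 and xn_sol <= 0) or (g > 0 and xn_gel <= 0):
            raise DomainError("zero per-phase xn with nonzero phase fraction")
        denom = (s / xn_sol if s > 0 else 0.0) + (g / xn_gel if g > 0 else 0.0)
        xn = 1.0 / denom
    if xw_sol is not None and xw_gel is not None:
        xw = s * xw_sol + g * xw_gel
    if beta_sol is not None and beta_gel is not None:
        beta = s * beta_sol + g * beta_gel
    return SimpleNamespace(xn=xn, xw=xw, beta=beta)


def gel_phase_beta(beta: float, s: float, beta_sol: float = 0.0) -> float:
    """Invert the mixing relation for the gel-phase crosslinking index.

    ``beta'' = (beta - s*beta') / g`` with ``g = 1 - s``; with a purely
    monomeric sol (``beta' = 0``) at ``beta = 2`` this gives
    ``2 / (1 - exp(-2)) ~= 2.313`` link-ends per gel neuron.
    """
    g = 1.0 - s
    if g <= 0:
        raise DomainError(f"gel fraction must be positive to carry beta, got g={g}")
    return (beta - s * beta_sol) / g


def redundancy(N: float, beta: float) -> RedundancyResult:
    """Linkage bookkeeping: ``N*beta`` total link-ends, ``D = N*(beta - 1)``.

    D counts loop-forming link-ends beyond the tree skeleton; at ``beta = 2``
    (maximum tree) D equals N.  For ``beta < 1`` the formula returns a
    negative D with a warning: the bookkeeping is stated for the post-gel
    regime but remains well defined.
    """
    if N < 1:
        raise DomainError(f"system size N must be >= 1, got {N}")
    if beta < 0:
        raise DomainError(f"beta must be >= 0, got {beta}")
    if beta < 1:
        warnings.warn(
            f"redundancy is negative for beta={beta} < 1 (pre-gel); the relation "
            "D = N*(beta - 1) is meant for the post-gel regime",
            stacklevel=2,
        )
    return RedundancyResult(total_linkages=N * beta, D=N * (beta - 1.0))
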
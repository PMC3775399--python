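"""Cascade-PGF oracle for the finite weight-average DP.

The finite-system weight average can be built without the closed-form
geometric sum: root a branching cascade at a uniformly chosen unit, give the
root the probability generating function ``theta * (1 - alpha + alpha*u)**f``
(f sites, each reacted with probability alpha), give each of the k subsequent
generations the transformer PGF ``theta * (1 - alpha + alpha*u)**(f-1)``
(one site is spent on the parent bond), and terminate the deepest generation
with the identity ``u = theta``.  The derivative of the compounded PGF at
``theta = 1`` is the expected mass seen from a random unit, i.e. the
weight-average DP.

The derivative is evaluated numerically by complex-step differentiation,
keeping this module an independent cross-check on the closed form in
:mod:`ffst.core` rather than a re-derivation of it.  It is guarded to small
instances: it is a test device, not a production path.
"""

from __future__ import annotations

from .errors import DomainError

_MAX_F = 10
_MAX_K = 12
_STEP = 1e-40


def cascade_xw_oracle(alpha: float, f: int, k: int) -> float:
    """Weight-average DP from the k-fold compounded binomial PGF.

    Must agree with ``weight_avg_dp(beta=(f-1)*alpha, k, f, exact=True)`` to
    better than 1e-8 on its guarded domain (f <= 10, k <= 12).
    """
    if not 0.0 <= alpha <= 1.0:
        raise DomainError(f"alpha must lie in [0, 1], got {alpha}")
    if not 2 <= f <= _MAX_F:
        raise DomainError(f"oracle guard: f must lie in [2, {_MAX_F}], got {f}")
    if not 0 <= k <= _MAX_K:
        raise DomainError(f"oracle guard: k must lie in [0, {_MAX_K}], got {k}")
    theta = complex(1.0, _STEP)
    u = theta  # deepest generation: bare unit, no further branching
    for _ in range(k):
        u = theta * (1.0 - alpha + alpha * u) ** (f - 1)
    w = theta * (1.0 - alpha + alpha * u) ** f
    return w.imag / _STEP
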
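"""Shifted orthonormal Legendre polynomials and their rank transforms.

The basis used throughout is ``Leg_j``, the *j*-th shifted Legendre
polynomial on [0, 1] normalised to unit L2 norm::

    Leg_j(u) = sqrt(2j + 1) * P_j(2u - 1),

with ``P_j`` the classical Legendre polynomial.  Composing with a
continuous prior CDF ``G`` gives the rank polynomials

    T_j(theta; G) = Leg_j(G(theta)),

which are orthonormal in L2(G) for *any* continuous G -- the property the
whole correction machinery rests on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["leg", "leg_matrix", "rank_poly", "RankTransformBasis", "DEFAULT_MAX_ORDER"]

DEFAULT_MAX_ORDER = 10


def _check_unit_interval(u: np.ndarray) -> None:
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("u must lie in [0, 1]")


def leg(j: int, u) -> np.ndarray | float:
    """Evaluate the shifted orthonormal Legendre polynomial of order ``j``.

    Parameters
    ----------
    j : int
        Polynomial order, ``j >= 0``.
    u : float or array_like
        Points in [0, 1].

    Returns
    -------
    float or ndarray
        ``sqrt(2j+1) * P_j(2u - 1)``, evaluated by the stable three-term
        recurrence on the classical polynomials.
    """
    if j < 0:
        raise ValueError("polynomial order j must be nonnegative")
    u_arr = np.asarray(u, dtype=float)
    _check_unit_interval(u_arr)
    x = 2.0 * u_arr - 1.0
    p_prev = np.ones_like(x)
    if j == 0:
        out = p_prev
    else:
        p_curr = x.copy()
        for n in range(1, j):
            # (n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}
            p_next = ((2 * n + 1) * x * p_curr - n * p_prev) / (n + 1)
            p_prev, p_curr = p_curr, p_next
        out = p_curr
    out = np.sqrt(2.0 * j + 1.0) * out
    if np.isscalar(u) or np.ndim(u) == 0:
        return float(out)
    return out


def leg_matrix(max_order: int, u) -> np.ndarray:
    """Evaluate Leg_1 .. Leg_max_order at ``u`` in one recurrence sweep.

    Returns an array of shape ``(max_order, len(u))``; row ``j-1`` holds
    ``Leg_j(u)``.  Order 0 (the constant 1) is deliberately omitted since
    every series in the model starts at j = 1.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    _check_unit_interval(u_arr)
    x = 2.0 * u_arr - 1.0
    rows = np.empty((max_order, x.size))
    p_prev = np.ones_like(x)
    p_curr = x.copy()
    for j in range(1, max_order + 1):
        rows[j - 1] = np.sqrt(2.0 * j + 1.0) * p_curr
        p_next = ((2 * j + 1) * x * p_curr - j * p_prev) / (j + 1)
        p_prev, p_curr = p_curr, p_next
    return rows


def rank_poly(j: int, theta, family) -> np.ndarray | float:
    """Rank polynomial ``T_j(theta; G) = Leg_j(G(theta))``.

    ``family`` is anything exposing a ``cdf`` method (a
    :class:`~dsbayes.families.ConjugateFamily` or a frozen scipy
    distribution).  Support endpoints map to u = 0 or 1 exactly.
    """
    u = family.cdf(theta)
    return leg(j, u)


@dataclass(frozen=True)
class RankTransformBasis:
    """The orthonormal system {T_j(.; G)} up to a maximum order.

    Attributes
    ----------
    cdf : callable
        The continuous CDF G of the anchor prior.
    max_order : int
        Highest order j supported.
    """

    cdf: Callable[[np.ndarray], np.ndarray]
    max_order: int = DEFAULT_MAX_ORDER

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be positive")

    def __call__(self, j: int, theta) -> np.ndarray | float:
        if j > self.max_order:
            raise ValueError(f"order {j} exceeds max_order={self.max_order}")
        if j == 0:
            theta_arr = np.asarray(theta, dtype=float)
            return 1.0 if theta_arr.ndim == 0 else np.ones_like(theta_arr)
        return leg(j, self.cdf(theta))

    def matrix(self, theta) -> np.ndarray:
        """All orders 1..max_order at once, shape (max_order, len(theta))."""
        return leg_matrix(self.max_order, self.cdf(theta))
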
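"""Geometric intensity-transition model for quantized white-matter pixels.

The detector's stochastic core models the state drop between two adjacent
in-mask pixels.  With intensities quantized into states ``s_0 .. s_N``, the
probability that a pixel and its (darker) neighbour share a state is ``q``,
and the conditional probability of dropping exactly ``k`` states is
``q * alpha**k``.  Normalization over all possible drops from the top state
forces ``alpha`` to be the unique root in (0, 1) of

    q * alpha**(n + 1) - alpha + (1 - q) = 0

so the model has a single free parameter ``q``, estimable from data as the
fraction of 8-connected neighbour pairs with equal states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InfeasibleModelError",
    "DegenerateMaskError",
    "StateSpace",
    "TransitionModel",
    "solve_alpha",
    "transition_probabilities",
    "estimate_q",
    "significant_transitions",
]

# 8-connectivity half-offsets: each unordered neighbour pair counted once.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


class InfeasibleModelError(ValueError):
    """No decay rate in (0, 1) exists for the requested (q, n) pair."""


class DegenerateMaskError(ValueError):
    """Mask has no adjacent in-mask pixel pairs to estimate q from."""


@dataclass(frozen=True)
class StateSpace:
    """N + 1 equal-width intensity intervals over normalized [0, 1].

    Intervals are half-open ``[a, b)`` except the last, which is closed,
    so every normalized intensity maps to exactly one state.
    """

    n_states: int
    edges: np.ndarray = field(repr=False)

    def __init__(self, n_states: int):
        if n_states < 2:
            raise ValueError(f"need at least 2 states, got {n_states}")
        object.__setattr__(self, "n_states", int(n_states))
        object.__setattr__(self, "edges", np.linspace(0.0, 1.0, n_states + 1))

    @property
    def n(self) -> int:
        """Highest state index N (= n_states - 1)."""
        return self.n_states - 1

    def assign(self, normalized: np.ndarray) -> np.ndarray:
        """Map normalized intensities in [0, 1] to integer states 0..N."""
        x = np.asarray(normalized, dtype=float)
        states = np.floor(x * self.n_states).astype(np.int64)
        # the closed upper end of the last interval
        return np.clip(states, 0, self.n)


def _characteristic(alpha: float, q: float, n: int) -> float:
    return q * alpha ** (n + 1) - alpha + (1.0 - q)


def solve_alpha(q: float, n: int, *, tol: float = 1e-12) -> float:
    """Unique root in (0, 1) of ``q*a**(n+1) - a + (1-q) = 0``.

    ``a = 1`` is always a root but violates normalization and is rejected.
    A root strictly inside (0, 1) exists iff ``q > 1/(n+1)``; outside that
    domain the pair is reported as infeasible rather than returning the
    boundary root.

    Parameters
    ----------
    q : float
        Same-state probability, strictly inside (0, 1).
    n : int
        Highest state index (number of states minus one), >= 1.

    Returns
    -------
    float
        The decay rate alpha in (0, 1), to absolute tolerance ~1e-12.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie strictly in (0, 1), got {q}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    eps = 1e-12
    lo, hi = eps, 1.0 - eps
    f_lo = _characteristic(lo, q, n)
    # Scan for the sign change; f(0+) = 1-q > 0 and f(1) = 0, so a root in
    # (0, 1) shows up as an interval where f goes negative.
    grid = np.linspace(lo, hi, 4096)
    values = q * grid ** (n + 1) - grid + (1.0 - q)
    sign_change = np.nonzero(np.sign(values[:-1]) != np.sign(values[1:]))[0]
    if sign_change.size == 0:
        raise InfeasibleModelError(
            f"infeasible (q, n) pair: q={q}, n={n} admits no root in (0, 1); "
            f"requires q > 1/(n+1) = {1.0 / (n + 1):.6g}"
        )
    i = int(sign_change[0])
    a, b = float(grid[i]), float(grid[i + 1])
    if values[i] == 0.0:
        return a
    root = brentq(_characteristic, a, b, args=(q, n), xtol=tol)
    if not 0.0 < root < 1.0 - 1e-9:
        raise InfeasibleModelError(
            f"infeasible (q, n) pair: q={q}, n={n} yields boundary root {root}"
        )
    assert f_lo > 0.0  # f(0+) = 1-q, guaranteed by the q-domain check
    return float(root)


def transition_probabilities(q: float, n: int) -> np.ndarray:
    """Vector ``[q, q*a, ..., q*a**n]`` of drop-size probabilities.

    Index ``k`` is the conditional probability of a drop of exactly ``k``
    states from the brighter pixel to its neighbour; the vector sums to 1.
    """
    alpha = solve_alpha(q, n)
    probs = q * alpha ** np.arange(n + 1, dtype=float)
    return probs


@dataclass(frozen=True)
class TransitionModel:
    """Fitted one-parameter geometric transition law.

    Attributes
    ----------
    q : float
        Probability that two adjacent in-mask pixels share a state.
    alpha : float
        Geometric decay rate, the unique root in (0, 1) of the
        normalization polynomial.
    n : int
        Highest state index N.
    probs : np.ndarray
        ``probs[k] = q * alpha**k``, the drop-size distribution.
    """

    q: float
    alpha: float
    n: int
    probs: np.ndarray = field(repr=False)

    @classmethod
    def from_q(cls, q: float, n: int) -> "TransitionModel":
        alpha = solve_alpha(q, n)
        probs = q * alpha ** np.arange(n + 1, dtype=float)
        return cls(q=float(q), alpha=alpha, n=int(n), probs=probs)

    def prob_drop(self, k: int | np.ndarray) -> np.ndarray:
        """Conditional probability of a drop of exactly ``|k|`` states."""
        k = np.abs(np.asarray(k))
        if np.any(k > self.n):
            raise ValueError(f"drop size exceeds n={self.n}")
        return self.probs[k]

    def min_significant_drop(self, threshold: float) -> int | None:
        """Smallest drop size whose probability falls below ``threshold``.

        Returns None when no drop (including 0) is that rare.  Because the
        drop-size distribution is strictly decreasing, every larger drop is
        rare as well.
        """
        below = np.nonzero(self.probs < threshold)[0]
        return int(below[0]) if below.size else None

    def significant_transitions(self, threshold: float) -> set[tuple[int, int]]:
        return significant_transitions(self, threshold)


def significant_transitions(
    model: TransitionModel, threshold: float
) -> set[tuple[int, int]]:
    """Ordered state pairs (s_a, s_b), a > b, with rare transition probability.

    A pair is significant when ``q * alpha**(a - b) < threshold``; since the
    probability depends only on the drop size, the result is the union over
    all pairs whose drop reaches the minimal significant drop.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    d0 = model.min_significant_drop(threshold)
    pairs: set[tuple[int, int]] = set()
    if d0 is None:
        return pairs
    d0 = max(d0, 1)  # ordered pairs require a > b
    for a in range(model.n + 1):
        for b in range(a - d0 + 1):
            pairs.add((a, b))
    return pairs


def _as_state_array(states) -> np.ndarray:
    arr = getattr(states, "states", states)
    return np.asarray(arr)


def estimate_q(states, mask: np.ndarray | None = None) -> float:
    """Estimate q as the fraction of equal-state 8-connected neighbour pairs.

    Unordered pairs with both pixels in-mask are each counted once.  An
    estimate of exactly 0 or 1 is clamped into (0, 1) by ``1 / (P + 1)``
    for P pairs, so the decay rate stays solvable; clamping is reported via
    a warning.

    Parameters
    ----------
    states : ndarray or StateImage
        Integer state labels; out-of-mask pixels may be sentinel -1.
    mask : ndarray of bool, optional
        In-mask pixels.  Defaults to ``states >= 0``.
    """
    s = _as_state_array(states)
    if mask is None:
        mask = s >= 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != s.shape:
        raise ValueError("mask geometry mismatch with state image")
    equal = 0
    total = 0
    for dr, dc in NEIGHBOR_OFFSETS:
        a, b, ma, mb = _shifted_views(s, mask, dr, dc)
        valid = ma & mb
        total += int(valid.sum())
        equal += int((a[valid] == b[valid]).sum())
    if total == 0:
        raise DegenerateMaskError(
            "degenerate mask: no adjacent in-mask pixel pairs to estimate q"
        )
    q = equal / total
    if q == 0.0 or q == 1.0:
        import warnings

        clamp = 1.0 / (total + 1)
        clamped = clamp if q == 0.0 else 1.0 - clamp
        warnings.warn(
            f"q estimate {q:.0f} clamped to {clamped:.6g} ({total} pairs)",
            stacklevel=2,
        )
        q = clamped
    return q


def _shifted_views(s: np.ndarray, mask: np.ndarray, dr: int, dc: int):
    """Aligned views of (values, mask) for a pixel and its (dr, dc) neighbour."""
    rows, cols = s.shape
    r0, r1 = max(dr, 0), rows + min(dr, 0)
    c0, c1 = max(dc, 0), cols + min(dc, 0)
    a = s[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    b = s[r0:r1, c0:c1]
    ma = mask[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    mb = mask[r0:r1, c0:c1]
    return a, b, ma, mb
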
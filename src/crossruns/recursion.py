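"""Iterative computation of the exact joint (C, L) distribution.

The construction conditions on two auxiliary variables that are not
model parameters: ``S``, the side of the first observation, and ``F``,
the end position of the first crossing (``F = 1`` meaning no crossing
occurs).  Given ``S = 1``,

* ``P(F = 1 | S=1) = p**(n-1)`` — all remaining observations stay on the
  starting side, giving a single run ``(c=0, l=n)``;
* ``P(F = f | S=1) = p**(f-2) * q`` for ``f = 2..n`` — an initial
  success run of length ``f-1`` followed by the first failure.

After a first crossing ending at ``f``, the remaining ``n+1-f``
observations form the same problem on a shorter sequence that starts on
the *opposite* side.  If that shorter sequence contributes ``c'``
crossings and a longest run ``l'``, the full sequence has ``c = c' + 1``
crossings and longest run ``max(f-1, l')`` — the initial run dominates
exactly when it is at least as long as everything behind it.  Summing
over ``f`` with the weights above yields the distribution for length
``n`` from the distributions for all shorter lengths; the base case
``n = 1`` puts all mass on ``(c=0, l=1)``.

Everything is exact: Fractions for general ``p``, and plain integers in
the symmetric case ``p = 1/2`` on the times scale, where every weight is
an integer multiple of ``2**-(n-1)``.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .pmf import (
    COND_FAILURE,
    COND_NONE,
    COND_SUCCESS,
    PROBABILITY,
    TIMES,
    BernoulliSpec,
    ConditionalPair,
    JointPMF,
    Rational,
    _normalize_rational,
    _zeros,
    as_fraction,
)

__all__ = [
    "base_case",
    "first_crossing_weight",
    "joint_conditional",
    "conditional_matrices",
    "combine_unconditional",
    "joint_unconditional",
    "symmetric_joint",
    "SymmetricJointCache",
]


def base_case(scale: str = PROBABILITY, m: int = 2) -> ConditionalPair:
    """The ``n = 1`` pair: all mass on ``(c=0, l=1)`` on either side.

    A single observation has no crossings and one run of length one, so
    both conditional distributions are degenerate with weight 1 (the
    times factor ``m**0`` is also 1).
    """
    one = np.array([[1]], dtype=object)
    return ConditionalPair(
        JointPMF(1, one, scale=scale, m=m, conditioning=COND_SUCCESS),
        JointPMF(1, one, scale=scale, m=m, conditioning=COND_FAILURE),
    )


def first_crossing_weight(n: int, f: int, spec: BernoulliSpec, side: int = 1) -> Fraction:
    """``P(F = f | S = side)`` for a sequence of length ``n``.

    ``F = 1`` denotes no crossing.  For a starting success the weights
    are ``p**(n-1)`` (no crossing) and ``p**(f-2) * q`` for
    ``f = 2..n``; a starting failure interchanges p and q.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (1 <= f <= n):
        raise ValueError(f"f must be in 1..{n}, got {f}")
    if side not in (0, 1):
        raise ValueError(f"side must be 0 or 1, got {side}")
    p = spec.p if side == 1 else spec.q
    q = 1 - p
    if f == 1:
        return p ** (n - 1)
    return p ** (f - 2) * q


def _extend(pairs: list, p: Fraction) -> None:
    """Append the (S=1, S=0) weight matrices for length ``len(pairs)``.

    ``pairs[k]`` holds the probability-scale object arrays for length
    ``k``; the new length consumes every shorter pair.
    """
    n = len(pairs)
    q = 1 - p
    a1, a0 = _zeros(n), _zeros(n)
    if n == 1:
        a1[0, 0] = Fraction(1)
        a0[0, 0] = Fraction(1)
    else:
        # F = 1: no crossing, a single run through the whole sequence
        a1[0, n - 1] += p ** (n - 1)
        a0[0, n - 1] += q ** (n - 1)
        for f in range(2, n + 1):
            k = n + 1 - f  # length of the tail after the first crossing
            r = f - 1  # length of the initial run
            w1 = p ** (f - 2) * q
            w0 = q ** (f - 2) * p
            s1, s0 = pairs[k]
            # tail starts on the opposite side: S=1 uses the S=0 matrices
            _place(a1, s0, r, k, w1)
            _place(a0, s1, r, k, w0)
    pairs.append((a1, a0))


def _place(acc: np.ndarray, short: np.ndarray, r: int, k: int, w) -> None:
    """Add the shorter-sequence matrix into ``acc`` after a first crossing.

    The crossing adds one to every crossing count (rows shift down by
    one) and the overall longest run is ``max(r, l')``: tail runs not
    exceeding the initial run ``r`` collapse onto column ``l = r``,
    longer tail runs keep their length.
    """
    t = min(r, k)
    acc[1 : k + 1, r - 1] += w * short[:, :t].sum(axis=1)
    if r < k:
        acc[1 : k + 1, r:k] += w * short[:, r:k]


def conditional_matrices(n: int, p) -> list:
    """Probability-scale (S=1, S=0) matrices for every length 1..n.

    Returns a list indexed by length (entry 0 is None); exposed so
    callers that need a whole family of lengths — rule specificities,
    sensitivities over a range of n — build it once.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p = as_fraction(p)
    BernoulliSpec(p)  # validates the open interval
    pairs: list = [None]
    for _ in range(n):
        _extend(pairs, p)
    return pairs


def joint_conditional(
    n: int, p, scale: str = PROBABILITY, m: int = 2
) -> ConditionalPair:
    """The pair of joint (C, L) distributions given the starting side.

    Built iteratively from the one-observation base case; exact for any
    rational ``p``.  ``scale="times"`` returns weights multiplied by
    ``m**(n-1)``.
    """
    pairs = conditional_matrices(n, p)
    a1, a0 = pairs[n]
    pair = ConditionalPair(
        JointPMF(n, a1, conditioning=COND_SUCCESS, m=m),
        JointPMF(n, a0, conditioning=COND_FAILURE, m=m),
    )
    if scale == TIMES:
        pair = pair.rescale(TIMES, m)
    return pair


def combine_unconditional(pair: ConditionalPair, spec) -> JointPMF:
    """Mix the conditional pair with weights p and q.

    ``P(L=l, C=c) = P(L=l, C=c | S=1) * p + P(L=l, C=c | S=0) * q``;
    on the times scale this equals ``m**(n-1)`` times the unconditional
    probability.
    """
    if not isinstance(spec, BernoulliSpec):
        spec = BernoulliSpec(as_fraction(spec))
    w = spec.p * pair.given_success.weights + spec.q * pair.given_failure.weights
    n = pair.n
    w = np.array(
        [[_normalize_rational(v) for v in row] for row in w], dtype=object
    ).reshape(n, n)
    return JointPMF(n, w, scale=pair.scale, m=pair.m, conditioning=COND_NONE)


def joint_unconditional(n: int, p, scale: str = PROBABILITY, m: int = 2) -> JointPMF:
    """Unconditional joint (C, L) distribution for Bernoulli(p) sequences."""
    return combine_unconditional(joint_conditional(n, p, scale, m), p)


class SymmetricJointCache:
    """Iteratively built times-scale matrices for ``p = 1/2``, ``m = 2``.

    In the symmetric case the two conditional distributions coincide
    with the unconditional one, every first-crossing factor ``p*m`` and
    ``q*m`` equals 1, and all weights are integers summing to
    ``2**(n-1)``.  The cache retains every computed length, so a family
    of lengths (e.g. rule specificities over n = 10..100) costs one
    build.
    """

    def __init__(self) -> None:
        self._mats: list = [None]

    @property
    def max_n(self) -> int:
        return len(self._mats) - 1

    def extend(self, n: int) -> None:
        while self.max_n < n:
            k = self.max_n + 1
            a = _zeros(k)
            if k == 1:
                a[0, 0] = 1
            else:
                a[0, k - 1] += 1  # no crossing: weight (pm)**(k-1) = 1
                for f in range(2, k + 1):
                    _place(a, self._mats[k + 1 - f], f - 1, k + 1 - f, 1)
            self._mats.append(a)

    def matrix(self, n: int) -> np.ndarray:
        """The raw integer object array for length ``n`` (do not mutate)."""
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        self.extend(n)
        return self._mats[n]

    def joint(self, n: int) -> JointPMF:
        return JointPMF(
            n, self.matrix(n).copy(), scale=TIMES, m=2, conditioning=COND_NONE
        )


def symmetric_joint(n: int, cache: SymmetricJointCache | None = None) -> JointPMF:
    """Times-scale joint distribution at ``p = 1/2``: an exact integer matrix.

    Dividing by ``2**(n-1)`` gives the probabilities.  Pass a
    :class:`SymmetricJointCache` to amortize the build across many
    lengths.
    """
    if cache is None:
        cache = SymmetricJointCache()
    return cache.joint(n)
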
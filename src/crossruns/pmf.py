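"""Containers for exact joint (crossings, longest-run) distributions.

A binary sequence of length ``n`` has ``C`` crossings (adjacent unequal
pairs, ``0 <= C <= n-1``) and a longest run of length ``L`` (maximal
constant stretch, ``1 <= L <= n``).  :class:`JointPMF` holds the joint
distribution of ``(C, L)`` as an ``n x n`` matrix of exact rational
weights — rows are ``c = 0..n-1``, columns are ``l = 1..n``.

Two weight scales are supported:

``probability``
    weights are probabilities and sum to 1;
``times``
    weights are probabilities multiplied by ``m**(n-1)`` (multiplier
    ``m = 2`` by default), so that in the symmetric case ``p = 1/2``
    every weight is an integer and tiny magnitudes are avoided.

All arithmetic is exact: weights are Python ints or
:class:`fractions.Fraction`, never floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Mapping, Union

import numpy as np

Rational = Union[int, Fraction]

#: scale identifiers
PROBABILITY = "probability"
TIMES = "times"

#: conditioning identifiers (side of the first observation)
COND_SUCCESS = "S=1"
COND_FAILURE = "S=0"
COND_NONE = "unconditional"

_SCALES = (PROBABILITY, TIMES)
_CONDITIONINGS = (COND_SUCCESS, COND_FAILURE, COND_NONE)


def as_fraction(value) -> Fraction:
    """Convert ``value`` to an exact :class:`~fractions.Fraction`.

    Accepts ints, Fractions and strings (``"3/5"``, ``"0.6"``).  Floats
    are interpreted through their shortest decimal representation
    (``0.6`` becomes ``3/5``, not the nearest binary double), which is
    what a caller typing a decimal literal means.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    return Fraction(value)


def round_half_away(x: Rational, digits: int = 0) -> Fraction:
    """Round an exact rational to ``digits`` decimals, ties away from zero.

    Returned as an exact Fraction with denominator ``10**digits`` so the
    result can still be compared exactly.
    """
    x = as_fraction(x)
    scale = 10**digits
    scaled = x * scale
    if scaled >= 0:
        q = math.floor(scaled + Fraction(1, 2))
    else:
        q = -math.floor(-scaled + Fraction(1, 2))
    return Fraction(q, scale)


@dataclass(frozen=True)
class BernoulliSpec:
    """Success probability ``p`` of a single observation, held exactly.

    ``q = 1 - p`` is derived; ``p + q == 1`` holds exactly by
    construction.
    """

    p: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", as_fraction(self.p))
        if not (0 < self.p < 1):
            raise ValueError(f"p must lie strictly in (0, 1), got {self.p}")

    @property
    def q(self) -> Fraction:
        return 1 - self.p

    def swapped(self) -> "BernoulliSpec":
        """The spec with the roles of success and failure interchanged."""
        return BernoulliSpec(self.q)


def _zeros(n: int) -> np.ndarray:
    # object dtype keeps exact ints/Fractions; np.zeros seeds int 0 cells
    return np.zeros((n, n), dtype=object)


class JointPMF:
    """Exact joint distribution of (C, L) for sequences of length ``n``.

    Parameters
    ----------
    n
        Sequence length, ``n >= 1``.
    weights
        Either an ``(n, n)`` array-like (rows ``c = 0..n-1``, columns
        ``l = 1..n``) or a mapping ``(c, l) -> weight``; entries must be
        exact rationals (int / Fraction).
    scale
        ``"probability"`` or ``"times"``.
    m
        Times-representation multiplier (only meaningful on the times
        scale; kept so round trips preserve it).  Default 2.
    conditioning
        ``"S=1"``, ``"S=0"`` or ``"unconditional"`` — whether the
        distribution is conditional on the side of the first
        observation.
    """

    __slots__ = ("n", "scale", "m", "conditioning", "_w")

    def __init__(
        self,
        n: int,
        weights,
        *,
        scale: str = PROBABILITY,
        m: int = 2,
        conditioning: str = COND_NONE,
    ) -> None:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        if scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")
        if conditioning not in _CONDITIONINGS:
            raise ValueError(
                f"conditioning must be one of {_CONDITIONINGS}, got {conditioning!r}"
            )
        if m < 2:
            raise ValueError(f"multiplier m must be >= 2, got {m}")
        self.n = int(n)
        self.scale = scale
        self.m = int(m)
        self.conditioning = conditioning
        if isinstance(weights, Mapping):
            w = _zeros(n)
            for (c, l), v in weights.items():
                self._check_index(c, l)
                w[c, l - 1] = v
        else:
            w = np.asarray(weights, dtype=object)
            if w.shape != (n, n):
                raise ValueError(
                    f"weights must have shape ({n}, {n}), got {w.shape}"
                )
            w = w.copy()
        for v in w.flat:
            if not isinstance(v, (int, Fraction)) or isinstance(v, bool):
                raise TypeError(f"weights must be exact rationals, got {v!r}")
            if v < 0:
                raise ValueError(f"weights must be nonnegative, got {v}")
        self._w = w

    # -- basic access -------------------------------------------------

    def _check_index(self, c: int, l: int) -> None:
        if not (0 <= c <= self.n - 1):
            raise IndexError(f"c must be in 0..{self.n - 1}, got {c}")
        if not (1 <= l <= self.n):
            raise IndexError(f"l must be in 1..{self.n}, got {l}")

    def __getitem__(self, key: tuple) -> Rational:
        c, l = key
        self._check_index(c, l)
        return self._w[c, l - 1]

    @property
    def weights(self) -> np.ndarray:
        """The ``(n, n)`` object array; rows c = 0..n-1, columns l = 1..n."""
        return self._w

    def items(self) -> Iterator[tuple]:
        """Yield ``((c, l), weight)`` for the nonzero cells."""
        for c in range(self.n):
            for li in range(self.n):
                v = self._w[c, li]
                if v != 0:
                    yield (c, li + 1), v

    def __eq__(self, other) -> bool:
        if not isinstance(other, JointPMF):
            return NotImplemented
        return (
            self.n == other.n
            and self.scale == other.scale
            and (self.scale == PROBABILITY or self.m == other.m)
            and self.conditioning == other.conditioning
            and bool((self._w == other._w).all())
        )

    def __repr__(self) -> str:
        scale = self.scale if self.scale == PROBABILITY else f"times(m={self.m})"
        return (
            f"JointPMF(n={self.n}, scale={scale}, "
            f"conditioning={self.conditioning!r})"
        )

    # -- aggregation --------------------------------------------------

    def total_mass(self) -> Rational:
        return self._w.sum()

    def expected_total(self) -> Rational:
        """The mass the scale dictates: 1, or ``m**(n-1)`` on the times scale."""
        if self.scale == PROBABILITY:
            return Fraction(1)
        return self.m ** (self.n - 1)

    def marginal_crossings(self) -> np.ndarray:
        """Row sums: the marginal weight of ``C = c`` for c = 0..n-1."""
        return self._w.sum(axis=1)

    def marginal_longest_run(self) -> np.ndarray:
        """Column sums: the marginal weight of ``L = l``; index l-1 holds l."""
        return self._w.sum(axis=0)

    def box_mass(self, c_min: int, l_max: int) -> Rational:
        """Total weight of the box ``{C >= c_min, L <= l_max}``.

        This is the no-signal region of run-chart rules that alarm on
        few crossings or a long run.
        """
        if not (0 <= c_min <= self.n - 1):
            raise IndexError(f"c_min must be in 0..{self.n - 1}, got {c_min}")
        if not (1 <= l_max <= self.n):
            raise IndexError(f"l_max must be in 1..{self.n}, got {l_max}")
        return self._w[c_min:, :l_max].sum()

    def expectation_product(self) -> Fraction:
        """Exact ``E[C * L]`` (after normalizing the scale factor away)."""
        total = Fraction(0)
        for (c, l), v in self.items():
            total += c * l * v
        return Fraction(total, 1) / self.expected_total()

    # -- transforms ---------------------------------------------------

    def rescale(self, scale: str, m: int | None = None) -> "JointPMF":
        """Convert between probability and times scales.

        Multiplies (or divides) every weight by ``m**(n-1)``.  Round
        trips are exact.
        """
        if scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")
        m = self.m if m is None else int(m)
        if scale == self.scale and (scale == PROBABILITY or m == self.m):
            return self
        factor = m ** (self.n - 1)
        if self.scale == PROBABILITY:
            w = self._w * factor
        else:
            w = self._w * Fraction(1, self.m ** (self.n - 1))
            if scale == TIMES:
                w = w * factor
        w = np.array(
            [[_normalize_rational(v) for v in row] for row in w], dtype=object
        ).reshape(self.n, self.n)
        return JointPMF(self.n, w, scale=scale, m=m, conditioning=self.conditioning)

    def as_floats(self) -> np.ndarray:
        """Float view of the matrix (display/plotting; not for arithmetic)."""
        return self._w.astype(float)

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        """Check normalization and the support constraint; raise on failure.

        ``c`` crossings split the sequence into ``c + 1`` runs, so the
        longest run satisfies ``ceil(n / (c+1)) <= l <= n - c`` wherever
        the weight is positive.
        """
        total = self.total_mass()
        if total != self.expected_total():
            raise AssertionError(
                f"total mass {total} != expected {self.expected_total()}"
            )
        for (c, l), _ in self.items():
            lo = -(-self.n // (c + 1))
            hi = self.n - c
            if not (lo <= l <= hi):
                raise AssertionError(
                    f"support violation at (c={c}, l={l}): "
                    f"expected {lo} <= l <= {hi} for n={self.n}"
                )


def _normalize_rational(v: Rational) -> Rational:
    """Collapse integral Fractions to plain ints (cheaper, prints cleanly)."""
    if isinstance(v, Fraction) and v.denominator == 1:
        return v.numerator
    return v


@dataclass(frozen=True)
class ConditionalPair:
    """The pair of joint distributions conditional on the first observation.

    The iterative recursion propagates this unit: the distribution given
    a starting success (``S=1``) and given a starting failure (``S=0``),
    for the same ``n`` and scale.
    """

    given_success: JointPMF
    given_failure: JointPMF

    def __post_init__(self) -> None:
        a, b = self.given_success, self.given_failure
        if a.conditioning != COND_SUCCESS or b.conditioning != COND_FAILURE:
            raise ValueError(
                "members must carry conditioning S=1 and S=0 respectively"
            )
        if a.n != b.n:
            raise ValueError(f"members disagree on n: {a.n} != {b.n}")
        if a.scale != b.scale or (a.scale == TIMES and a.m != b.m):
            raise ValueError("members disagree on scale")

    @property
    def n(self) -> int:
        return self.given_success.n

    @property
    def scale(self) -> str:
        return self.given_success.scale

    @property
    def m(self) -> int:
        return self.given_success.m

    def rescale(self, scale: str, m: int | None = None) -> "ConditionalPair":
        return ConditionalPair(
            self.given_success.rescale(scale, m),
            self.given_failure.rescale(scale, m),
        )


# thin functional aliases for the container operations


def marginal_crossings(pmf: JointPMF) -> np.ndarray:
    """Marginal weights of the number of crossings (row sums over l)."""
    return pmf.marginal_crossings()


def marginal_longest_run(pmf: JointPMF) -> np.ndarray:
    """Marginal weights of the longest-run length (column sums over c)."""
    return pmf.marginal_longest_run()


def box_mass(pmf: JointPMF, c_min: int, l_max: int) -> Rational:
    """Total weight of ``{C >= c_min, L <= l_max}``."""
    return pmf.box_mass(c_min, l_max)


def rescale(pmf: JointPMF, scale: str, m: int | None = None) -> JointPMF:
    """Convert a distribution between probability and times scales."""
    return pmf.rescale(scale, m)
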
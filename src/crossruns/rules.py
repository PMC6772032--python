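"""Anhoej run-chart rules: limits, specificity and sensitivity.

Run charts flag non-random variation with two tests on the ``n`` useful
observations (points not on the centre line):

* **shift rule** — signal if any run is longer than
  ``round(log2(n) + 3)`` (nearest integer);
* **crossings rule** — signal if the curve crosses the centre line
  fewer times than the lower 5th percentile of Binomial(n-1, 1/2).

Because the joint distribution of crossings and longest run is
available exactly, the operating characteristics of the combined rules
are exact too: the specificity at length ``n`` is the probability mass
of the no-signal box ``{C >= ca(n), L <= la(n)}`` under ``p = 1/2``,
and the sensitivity toward a shifted process is one minus the same box
mass under the shifted ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .pmf import PROBABILITY, JointPMF
from .recursion import SymmetricJointCache, joint_unconditional

__all__ = [
    "RuleLimits",
    "shift_limit",
    "crossings_limit",
    "limits_for",
    "apply_rules",
    "specificity",
    "sensitivity",
    "specificity_table",
]


@dataclass(frozen=True)
class RuleLimits:
    """Non-signalling limits for ``n`` useful observations.

    A chart signals iff ``l > longest_run_limit`` or
    ``c < crossings_limit``.
    """

    n: int
    longest_run_limit: int
    crossings_limit: int


def shift_limit(n: int) -> int:
    """Longest run tolerated: ``log2(n) + 3`` rounded to nearest integer.

    Ties round away from zero, though for integer ``n`` the fractional
    part of ``log2(n)`` is never exactly one half.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return int(math.floor(math.log2(n) + 3 + 0.5))


def crossings_limit(n: int) -> int:
    """Fewest crossings tolerated: lower 5th percentile of Binomial(n-1, 1/2).

    The smallest integer ``k`` with ``CDF(k; n-1, 1/2) >= 0.05``,
    computed in exact integer arithmetic
    (``20 * sum_{j<=k} C(n-1, j) >= 2**(n-1)``); a chart signals iff
    ``C < k``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    target = 2 ** (n - 1)
    cum = 0
    for k in range(n):
        cum += math.comb(n - 1, k)
        if 20 * cum >= target:
            return k
    raise AssertionError("unreachable: CDF reaches 1")


def limits_for(n: int) -> RuleLimits:
    """Both Anhoej limits for ``n`` useful observations."""
    return RuleLimits(
        n=n, longest_run_limit=shift_limit(n), crossings_limit=crossings_limit(n)
    )


def apply_rules(c: int, l: int, limits: RuleLimits) -> bool:
    """True iff a chart with ``c`` crossings and longest run ``l`` signals."""
    n = limits.n
    if not (0 <= c <= n - 1):
        raise ValueError(f"c must be in 0..{n - 1}, got {c}")
    if not (1 <= l <= n):
        raise ValueError(f"l must be in 1..{n}, got {l}")
    return l > limits.longest_run_limit or c < limits.crossings_limit


def _no_signal_mass(pmf: JointPMF, limits: RuleLimits) -> Fraction:
    """Probability of the no-signal box under ``pmf`` (any scale)."""
    n = pmf.n
    c_min = min(limits.crossings_limit, n - 1)
    l_max = min(limits.longest_run_limit, n)
    mass = pmf.box_mass(c_min, l_max)
    return Fraction(mass) / Fraction(pmf.expected_total())


def specificity(n: int, cache: SymmetricJointCache | None = None) -> Fraction:
    """Exact probability that a random (p = 1/2) chart does not signal.

    Computed from the symmetric joint distribution; pass a shared cache
    when evaluating many lengths.
    """
    if cache is None:
        cache = SymmetricJointCache()
    return _no_signal_mass(cache.joint(n), limits_for(n))


def sensitivity(n: int, p) -> Fraction:
    """Exact probability that a Bernoulli(p) chart signals.

    At ``p = 1/2`` this is one minus the specificity, by definition.
    """
    pmf = joint_unconditional(n, p, scale=PROBABILITY)
    return 1 - _no_signal_mass(pmf, limits_for(n))


def specificity_table(
    n_min: int, n_max: int, cache: SymmetricJointCache | None = None
) -> list:
    """``(n, exact specificity)`` for every length in ``n_min..n_max``."""
    if n_min < 2 or n_max < n_min:
        raise ValueError(f"need 2 <= n_min <= n_max, got {n_min}..{n_max}")
    if cache is None:
        cache = SymmetricJointCache()
    cache.extend(n_max)
    return [(n, specificity(n, cache)) for n in range(n_min, n_max + 1)]
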
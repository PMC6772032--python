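"""Joint (C, L) distribution when the success probability varies by position.

Observations remain independent, but observation ``i`` succeeds with its
own probability ``p_i``.  The recursion generalizes by running over
*suffixes* of the probability vector: after a first crossing ending at
absolute position ``f``, the remaining observations are literally the
suffix starting at ``f``, conditioned on starting on the opposite side.
Given a start at position ``k`` on the success side, the first-crossing
weights become

* no crossing: ``prod(p_i for i in k+1..n)``;
* crossing ending at ``f``: ``prod(p_i for i in k+1..f-1) * (1 - p_f)``,

with complements throughout for a start on the failure side.  The Case
placement (``c' + 1`` crossings, longest run ``max(f-k, l')``) is
unchanged.  A constant vector reproduces the fixed-p recursion exactly.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np

from .pmf import (
    COND_FAILURE,
    COND_NONE,
    COND_SUCCESS,
    PROBABILITY,
    TIMES,
    ConditionalPair,
    JointPMF,
    _normalize_rational,
    _zeros,
    as_fraction,
)
from .recursion import _place

__all__ = ["validate_probs", "joint_conditional_varying", "joint_unconditional_varying"]


def validate_probs(probs: Sequence) -> list:
    """Coerce to a list of exact Fractions, all strictly inside (0, 1)."""
    out = [as_fraction(p) for p in probs]
    if not out:
        raise ValueError("probability vector must be non-empty")
    for i, p in enumerate(out, start=1):
        if not (0 < p < 1):
            raise ValueError(
                f"probability at position {i} must lie strictly in (0, 1), got {p}"
            )
    return out


def joint_conditional_varying(
    probs: Sequence, scale: str = PROBABILITY, m: int = 2
) -> ConditionalPair:
    """Conditional pair for per-position success probabilities.

    ``probs[i-1]`` is the success probability of observation ``i``.
    ``S`` refers to the side of the first observation.  Exact; suffix
    pairs are built from the end of the vector backwards.
    """
    probs = validate_probs(probs)
    n = len(probs)
    # suffix[s] = (S=1, S=0) matrices for the suffix starting at 1-based s
    suffix: list = [None] * (n + 2)
    for s in range(n, 0, -1):
        length = n - s + 1
        a1, a0 = _zeros(length), _zeros(length)
        if length == 1:
            a1[0, 0] = Fraction(1)
            a0[0, 0] = Fraction(1)
        else:
            w1 = Fraction(1)  # running prod of p_i, i = s+1 .. f-1
            w0 = Fraction(1)  # running prod of (1 - p_i)
            for f in range(s + 1, n + 1):
                pf = probs[f - 1]
                r = f - s  # initial run length
                k = n - f + 1  # tail length
                s1, s0 = suffix[f]
                _place(a1, s0, r, k, w1 * (1 - pf))
                _place(a0, s1, r, k, w0 * pf)
                w1 *= pf
                w0 *= 1 - pf
            # no crossing: the whole suffix is one run; after the loop the
            # running products cover every position s+1..n on the start side
            a1[0, length - 1] += w1
            a0[0, length - 1] += w0
        suffix[s] = (a1, a0)
    a1, a0 = suffix[1]
    pair = ConditionalPair(
        JointPMF(n, a1, conditioning=COND_SUCCESS, m=m),
        JointPMF(n, a0, conditioning=COND_FAILURE, m=m),
    )
    if scale == TIMES:
        pair = pair.rescale(TIMES, m)
    return pair


def joint_unconditional_varying(
    probs: Sequence, scale: str = PROBABILITY, m: int = 2
) -> JointPMF:
    """Unconditional joint distribution; the mixture weight is ``p_1``."""
    probs = validate_probs(probs)
    pair = joint_conditional_varying(probs, scale, m)
    p1 = probs[0]
    w = p1 * pair.given_success.weights + (1 - p1) * pair.given_failure.weights
    n = pair.n
    w = np.array(
        [[_normalize_rational(v) for v in row] for row in w], dtype=object
    ).reshape(n, n)
    return JointPMF(n, w, scale=pair.scale, m=pair.m, conditioning=COND_NONE)
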
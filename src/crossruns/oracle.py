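"""Brute-force enumeration and Monte-Carlo simulation of (C, L).

This module is the ground truth the recursion is validated against: it
never shares code with the iterative procedure.  ``enumerate_joint``
walks every binary sequence and accumulates exact product weights;
``simulate_joint`` draws charts with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import groupby
from typing import Sequence

import numpy as np

from .pmf import (
    COND_FAILURE,
    COND_NONE,
    COND_SUCCESS,
    JointPMF,
    as_fraction,
)
from .varying import validate_probs

__all__ = [
    "SequenceStats",
    "sequence_stats",
    "enumerate_joint",
    "SimulationResult",
    "simulate_joint",
    "DEFAULT_ENUMERATION_CAP",
]

#: largest n enumerated by default (2**16 sequences; exact and instant)
DEFAULT_ENUMERATION_CAP = 16


@dataclass(frozen=True)
class SequenceStats:
    """Crossings count and longest-run length of one concrete sequence."""

    n: int
    c: int
    l: int


def sequence_stats(seq: Sequence[int]) -> SequenceStats:
    """Count crossings and the longest run in a 0/1 sequence.

    A crossing is a pair of adjacent unequal values; a run is a maximal
    constant stretch.
    """
    seq = list(seq)
    if not seq:
        raise ValueError("sequence must be non-empty")
    if any(v not in (0, 1) for v in seq):
        raise ValueError("sequence values must be 0 or 1")
    c = sum(a != b for a, b in zip(seq, seq[1:]))
    l = max(len(list(g)) for _, g in groupby(seq))
    return SequenceStats(n=len(seq), c=c, l=l)


def enumerate_joint(
    n: int,
    probs,
    condition: int | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> JointPMF:
    """Exact joint distribution by exhaustive enumeration.

    Parameters
    ----------
    n
        Sequence length.
    probs
        A scalar success probability or a length-``n`` vector of
        per-position probabilities.
    condition
        ``1`` or ``0`` fixes the first observation (conditional
        distribution given the starting side); ``None`` enumerates both
        sides weighted by ``p_1`` / ``1 - p_1``.
    cap
        Guard on the 2**n cost; raise it explicitly for larger n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > cap:
        raise ValueError(
            f"n={n} exceeds the enumeration cap {cap} (2**n sequences); "
            "pass a larger cap explicitly if you really want this"
        )
    if condition not in (None, 0, 1):
        raise ValueError(f"condition must be None, 0 or 1, got {condition}")
    try:
        probs = validate_probs([as_fraction(probs)] * n)
    except TypeError:
        probs = validate_probs(probs)
    if len(probs) != n:
        raise ValueError(f"expected {n} probabilities, got {len(probs)}")

    weights: dict = {}
    firsts = (condition,) if condition is not None else (0, 1)
    for first in firsts:
        for code in range(2 ** (n - 1)):
            seq = [first] + [(code >> i) & 1 for i in range(n - 1)]
            w = Fraction(1)
            # position 1 contributes only unconditionally
            start = 1 if condition is not None else 0
            for i in range(start, n):
                w *= probs[i] if seq[i] == 1 else 1 - probs[i]
            st = sequence_stats(seq)
            key = (st.c, st.l)
            weights[key] = weights.get(key, 0) + w

    conditioning = (
        COND_NONE
        if condition is None
        else (COND_SUCCESS if condition == 1 else COND_FAILURE)
    )
    return JointPMF(n, weights, conditioning=conditioning)


@dataclass(frozen=True)
class SimulationResult:
    """Empirical joint distribution plus the C*L summary of a simulation."""

    pmf: JointPMF  # empirical frequencies as exact fractions count/reps
    mean_cl: float
    se_cl: float
    reps: int
    seed: int

    @property
    def n(self) -> int:
        return self.pmf.n


def simulate_joint(n: int, p, reps: int, seed: int) -> SimulationResult:
    """Draw ``reps`` independent Bernoulli(p) charts of length ``n``.

    Returns the empirical (C, L) frequencies (exact fractions with
    denominator ``reps``, so they sum to 1) and the sample mean of
    ``C * L`` with its standard error.  The same seed reproduces the
    result bit-for-bit.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    pf = float(as_fraction(p))
    rng = np.random.default_rng(seed)
    x = rng.random((reps, n)) < pf

    if n == 1:
        c = np.zeros(reps, dtype=np.int64)
        l = np.ones(reps, dtype=np.int64)
    else:
        same = x[:, 1:] == x[:, :-1]
        c = (~same).sum(axis=1).astype(np.int64)
        cur = np.ones(reps, dtype=np.int64)
        l = np.ones(reps, dtype=np.int64)
        for i in range(n - 1):
            cur = np.where(same[:, i], cur + 1, 1)
            np.maximum(l, cur, out=l)

    keys, counts = np.unique(c * (n + 1) + l, return_counts=True)
    weights = {
        (int(k) // (n + 1), int(k) % (n + 1)): Fraction(int(cnt), reps)
        for k, cnt in zip(keys, counts)
    }
    cl = (c * l).astype(float)
    mean = float(cl.mean())
    if reps > 1:
        se = float(cl.std(ddof=1) / np.sqrt(reps))
    else:
        se = float("nan")
    return SimulationResult(
        pmf=JointPMF(n, weights, conditioning=COND_NONE),
        mean_cl=mean,
        se_cl=se,
        reps=reps,
        seed=seed,
    )
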
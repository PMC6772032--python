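# Methods

## Model and statistics

The data model is a sequence of `n` independent Bernoulli observations,
observation `i` succeeding with probability `p` (constant case) or `p_i`
(varying case). In the run-chart application a success is a point above
the centre line, which must come from *prior* data for independence to
hold; points exactly on the line are discarded beforehand, so `n` counts
the useful observations only. The two statistics are

- `C`, the number of crossings — adjacent unequal pairs, `0..n-1`;
- `L`, the longest run — the maximal constant stretch, `1..n`.

`c` crossings split the sequence into `c+1` runs, which forces the
support constraint `ceil(n/(c+1)) <= l <= n-c`; every computed matrix is
checked against it.

## The iterative recursion

Two auxiliary variables drive the computation; neither is a model
parameter. `S` is the side of the first observation, and `F` is the end
position of the first crossing, with `F = 1` denoting no crossing. Given
`S = 1`:

- `P(F=1 | S=1) = p^(n-1)` — the whole sequence is one run, contributing
  mass at `(c=0, l=n)`;
- `P(F=f | S=1) = p^(f-2) q` for `f = 2..n` — an initial run of length
  `f-1` and then the first point on the other side.

Conditional on a first crossing ending at `f`, the last `n+1-f`
observations are again an independent Bernoulli sequence — the same
problem at a shorter length — starting on the *opposite* side. If that
tail has `c'` crossings and longest run `l'`, the full sequence has
`c = c'+1` and `l = max(f-1, l')`. The code implements this single
placement rule; it covers both regimes of the construction (initial run
at least as long as the tail, where only the tail's crossings marginal
matters because `l` is pinned to `f-1`, and the opposite regime, where
tail runs up to `f-1` collapse onto the column `l = f-1` and longer tail
runs keep their length). Summing over `f` with the weights above builds
the conditional pair for length `n` from the pairs of *all* shorter
lengths, starting from the degenerate base `n = 1` (all mass at
`(0, 1)`). The pair conditional on `S = 0` interchanges `p` and `q`, and
the unconditional law is the mixture `p · P(·|S=1) + q · P(·|S=0)`.

All shorter-length pairs are retained during a build (each length
consumes every shorter one), so computing a family of lengths — as the
rule specificities over `n = 10..100` do — costs a single build;
`SymmetricJointCache` exposes exactly this reuse.

In the varying-probability case the tail after a crossing at absolute
position `f` is literally the suffix starting at `f`, so the recursion
runs over suffixes of the probability vector, with first-crossing
weights `prod(p_i, i = k+1..f-1) · (1-p_f)` for a suffix starting at `k`
on the success side (complements on the failure side). The construction
is direction-specific — no reversal symmetry is claimed — and a constant
vector reproduces the fixed-`p` recursion cell-for-cell. Since no
published closed form exists for this generalization, its correctness
evidence is exact agreement with exhaustive enumeration over seeded
random vectors.

## Exact arithmetic and the times scale

All reference computations use exact rationals: `fractions.Fraction`
for general `p`, plain arbitrary-precision integers in the symmetric
case. This removes any precision parameter from the method — results
are exact at every `n`, and the cost of longer sequences is time and
memory, not accuracy. Weights can be carried on two scales:

- **probability** — weights sum to 1;
- **times(m)** — weights multiplied by `m^(n-1)` (default `m = 2`), the
  scale on which the symmetric-case matrix is integer. The scale factor
  commutes with the recursion because the first-crossing weights factor
  as `(pm)^(f-2) (qm) m^(n-f)` and `pm = qm = 1` at `p = 1/2`.

Only `m = 2` is exercised by the tests; other multipliers are accepted
but cosmetic under exact arithmetic.

Conversions, marginals, box masses and serialization never pass through
floats. JSON/CSV entries are written as integer or `num/den` strings, so
write–read round trips are exact for any rational `p` (a decimal string
could not represent e.g. `p = 1/3` results exactly). Published
one-decimal and three-decimal reference values are compared after
rounding the exact rationals half-away-from-zero, implemented on
integers (`floor(10^d x + 1/2)`), and the rounded values are themselves
held as exact multiples of `10^-d` so the comparisons are equalities.

## Run-chart rules

For `n` useful observations the limits are

- longest-run limit `la(n) = round(log2(n) + 3)` (nearest integer;
  half-away, though exact halves cannot occur for integer `n`);
- crossings limit `ca(n)` = the smallest `k` with
  `CDF(k; n-1, 1/2) >= 0.05`, evaluated in integer arithmetic as
  `20 · sum_{j<=k} C(n-1, j) >= 2^(n-1)` — the standard lower-quantile
  convention, which is also the convention that reproduces the published
  three-decimal specificity table at every `n` in `10..100`.

A chart signals iff `L > la(n)` or `C < ca(n)`. Specificity is the exact
no-signal mass `P(C >= ca, L <= la)` at `p = 1/2`; sensitivity at a
shifted `p` is one minus the same box mass under that `p`. Specificity
is *not* monotone in `n` (the limits move in integer jumps), and the
package asserts nothing of the sort. For tiny `n` the limits can exceed
the attainable range (e.g. `la(2) = 4 > 2`); box bounds are clamped to
the index ranges, which is the correct probability statement (the rule
simply cannot fire).

## Validation design

Correctness rests on routes that share no code with the recursion:

- **Exhaustive enumeration** (`enumerate_joint`) walks every binary
  sequence, scores it with `sequence_stats`, and accumulates exact
  product weights. The recursion is compared cell-for-cell, exactly, for
  `n <= 12` at `p ∈ {0.3, 0.5, 0.8}` and for 20 seeded random
  probability vectors at `n <= 10`. The enumeration is capped at
  `n = 16` (65536 sequences) unless the caller raises the cap.
- **Closed forms**: corner cells `P(C=0, L=n) = p^n + q^n` and
  `P(C=n-1, L=1) = p^⌈n/2⌉ q^⌊n/2⌋ + p^⌊n/2⌋ q^⌈n/2⌉`; the
  first-crossing law telescopes to 1; the symmetric crossings marginal
  equals `C(n-1, c)` for all `n <= 100`.
- **Monte-Carlo** (`simulate_joint`): seeded `numpy` PCG64 generator,
  vectorized computation of (C, L) per replicate, bit-reproducible for a
  fixed seed. The exact `E[C·L]` at `n = 200`, `p = 1/2` — deliberately
  a demanding functional of the far tail — agrees with a 100 000-rep
  simulation within four standard errors.

The simulator emulates exactly the model the recursion assumes
(independent Bernoulli points around a known centre line). It does not
emulate the features real run-chart data may violate: a centre line
estimated from the *same* data (which induces dependence), observations
tied with the median, or autocorrelation. Passing tests therefore
certify the mathematics of the i.i.d. model, not robustness to those
violations; series with a same-data median or autocorrelation are out of
scope.

## Problem sizes and cost

Memory and time are cubic-to-quartic in `n` (all shorter matrices are
held; each has `O(n^2)` exact entries). Desk-scale choices used
throughout: full-matrix reference checks at `n = 16`; rule
specificities over `n = 10..100`; the binomial-marginal property to
`n = 100`; the simulation cross-check at `n = 200` (symmetric build
~6 s, 100 000 replicates). The CLI warns above `n = 200` about cost —
never about accuracy, which exact arithmetic fixes at any length.

## Known limitations

- The joint law is for a predetermined centre line only; the
  median-of-same-data and autocorrelated variants require different
  recursions and are not implemented.
- Exact rational arithmetic grows denominators for general `p`; very
  long sequences are better served on the times scale or, if speed ever
  dominates exactness, by a float build outside this package's scope.
- `sensitivity` models a step shift as a changed constant `p`; drifts
  or transient shifts would need the varying-probability machinery and
  a scenario definition.
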
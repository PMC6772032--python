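# crossruns

Exact joint distribution of the **number of crossings** and the **longest
run** in a sequence of independent Bernoulli observations, with exact
operating characteristics of run-chart rules built on top of it.

## The problem

A run chart plots observations around a centre line (typically a median
from earlier data). Writing 1 for a point above the line and 0 for a point
below, the *n* useful observations form an independent Bernoulli(*p*)
sequence. Two statistics summarize its randomness:

- **C** — the number of crossings: adjacent pairs on opposite sides
  (0 ≤ C ≤ n−1);
- **L** — the length of the longest run: the longest stretch of
  consecutive points on the same side (1 ≤ L ≤ n).

In the symmetric case *p* = ½, C alone is Binomial(n−1, ½), but no closed
form is known for L, let alone for the joint law of (C, L) — which is what
rules for separating signal from noise in statistical process control
actually need. `crossruns` computes P<sub>n</sub>(C = c, L = l) **exactly**
for any rational *p* (or a per-position probability vector), by an
iterative recursion over the end position F of the first crossing:
conditional on the starting side S, a first crossing ending at *f* leaves
a shorter sequence of n+1−f observations starting on the opposite side, so
the distribution for length *n* assembles from the already-computed
distributions of all shorter lengths, with weights
P(F=1|S=1) = p<sup>n−1</sup> and P(F=f|S=1) = p<sup>f−2</sup>q. All
arithmetic uses exact rationals; in the symmetric case the weights times
2<sup>n−1</sup> are plain integers (the *times* representation, multiplier
m = 2 by default).

From the joint law the package evaluates the **Anhøj run-chart rules**
exactly:

- *shift rule* — signal if any run is longer than round(log₂(n) + 3);
- *crossings rule* — signal if C is below the lower 5th percentile of
  Binomial(n−1, ½);

so the specificity at length *n* is the exact mass of the no-signal box
{C ≥ ca(n), L ≤ la(n)} at *p* = ½, and the sensitivity under a shifted
process is one minus that mass at the shifted *p*.

## Worked example

The times-scale joint distribution for n = 6, p = ½ (integers summing to
2⁵ = 32):

```
$ crossruns joint --n 6 --p 0.5 --scale times
# n=6
# scale=times
# m=2
# conditioning=unconditional
,l=1,l=2,l=3,l=4,l=5,l=6
c=0,0,0,0,0,0,1
c=1,0,0,1,2,2,0
c=2,0,1,6,3,0,0
c=3,0,6,4,0,0,0
c=4,0,5,0,0,0,0
c=5,1,0,0,0,0,0
```

Row c, column l holds 2⁵·P₆(C = c, L = l): for instance a single constant
run (c = 0, l = 6) has weight 1, i.e. probability 1/32 per starting side,
and row sums are the binomial coefficients C(5, c). Rule limits and exact
specificities over a range of lengths:

```
$ crossruns specificity --n-min 10 --n-max 12
n,specificity,specificity_exact
10,0.955,489/512
11,0.951,487/512
12,0.957,245/256
```

At n = 10 the limits are la = round(log₂10 + 3) = 6 and ca = 2, and a
random chart stays inside both limits with probability 489/512 ≈ 0.955.
The same quantities are available in Python:

```python
from fractions import Fraction
from crossruns import joint_unconditional, specificity

pmf = joint_unconditional(16, Fraction(1, 2))
pmf[7, 4]          # Fraction(679, 8192) ≈ 0.083, the modal cell
specificity(16)    # Fraction(31237, 32768)
```

Per-position probabilities (`joint-varying`), brute-force enumeration
(`oracle`, n ≤ 16) and a seeded simulator (`simulate`) round out the
toolkit; every exact computation is validated cell-for-cell against the
enumeration in the test suite.

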
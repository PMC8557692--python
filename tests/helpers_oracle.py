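"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths:

* ``exact_tail_log10`` sums the binomial tail in exact integer arithmetic
  (the float probability is treated as the exact dyadic rational it is), so
  the only inexactness is the final logarithm of big integers.
* ``brute_best_interval`` enumerates every subinterval with scipy's
  independent survival-function implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

_LN10 = math.log(10.0)


def exact_tail_log10_row(w: int, p: float) -> list[float]:
    """log10 P(X >= k) for k = 0..w by exact integer summation."""
    num, den = float(p).as_integer_ratio()  # p exactly num / den, den = 2**s
    if not 0 < num < den:
        raise ValueError("p must be strictly inside (0, 1)")
    a, b = num, den - num
    apow = [1] * (w + 1)
    bpow = [1] * (w + 1)
    for i in range(1, w + 1):
        apow[i] = apow[i - 1] * a
        bpow[i] = bpow[i - 1] * b
    log_den = w * math.log(den)
    out = [0.0] * (w + 1)
    s = 0
    for k in range(w, -1, -1):
        s += math.comb(w, k) * apow[k] * bpow[w - k]
        out[k] = (math.log(s) - log_den) / _LN10
    out[0] = 0.0  # the suffix sum at k=0 is exactly den**w
    return out


def exact_tail_log10(k: int, w: int, p: float) -> float:
    return exact_tail_log10_row(w, p)[k]


def brute_best_interval(seq: str, members: str, p: float, m: int, M: int):
    """Exhaustive minimum-tail subinterval search over a whole sequence.

    Returns (log10 tail, start, end), 1-based inclusive, with the package's
    tie rule (lowest tail, then longest, then leftmost), or None if the
    sequence is shorter than ``m``.  Uses scipy's logsf, not the package.
    """
    L = len(seq)
    if L < m:
        return None
    hits = np.array([c in members for c in seq], dtype=np.intp)
    pref = np.concatenate([[0], np.cumsum(hits)])
    best = None  # (logp, w, start offset)
    for w in range(m, min(M, L) + 1):
        k = pref[w:] - pref[: L - w + 1]
        lp = stats.binom.logsf(k - 1, w, p) / _LN10
        i = int(np.argmin(lp))
        v = float(lp[i])
        if best is None or v < best[0] or (v == best[0] and w > best[1]):
            best = (v, w, i)
    v, w, i = best
    return v, i + 1, i + w


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
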
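"""Log-space binomial tail probabilities.

Everything downstream scores a candidate region by the upper binomial tail
P(X >= k) for X ~ Binomial(w, p): the probability of seeing at least the
observed count of a residue (set) in a window of length w under the
background frequency p.  Tails are computed and carried in log10 space
end-to-end; linear space underflows long before proteome-scale scans do.

Terms are evaluated with log-gamma and combined with a cumulative
log-add-exp from the extreme tail inward, which involves only additions of
positive quantities (no cancellation).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

__all__ = ["log_binom_tail", "tail_table", "tail_row"]

_LN10 = math.log(10.0)


@lru_cache(maxsize=4096)
def _tail_row(w: int, p: float) -> np.ndarray:
    """log10 P(X >= k) for k = 0..w, X ~ Binomial(w, p). Read-only array."""
    i = np.arange(w + 1, dtype=np.float64)
    lpmf = (
        gammaln(w + 1.0)
        - gammaln(i + 1.0)
        - gammaln(w - i + 1.0)
        + i * math.log(p)
        + (w - i) * math.log1p(-p)
    )
    # suffix logsumexp: accumulate from i = w downward
    tail = np.logaddexp.accumulate(lpmf[::-1])[::-1] / _LN10
    np.minimum(tail, 0.0, out=tail)
    tail[0] = 0.0  # P(X >= 0) is exactly 1
    tail.setflags(write=False)
    return tail


def _check(k: int, w: int, p: float) -> None:
    if not 0 < p < 1:
        raise ValueError(f"degenerate null: p={p!r} must lie strictly in (0, 1)")
    if not 0 <= k <= w:
        raise ValueError(f"need 0 <= k <= w, got k={k}, w={w}")


def log_binom_tail(k: int, w: int, p: float) -> float:
    """log10 of the upper binomial tail P(X >= k), X ~ Binomial(w, p).

    Parameters
    ----------
    k : observed success count, 0 <= k <= w.
    w : window length (number of trials).
    p : background success probability, strictly inside (0, 1).
    """
    _check(k, w, p)
    return float(_tail_row(w, p)[k])


def tail_table(w_max: int, p: float):
    """Cached evaluator ``f(k, w) == log_binom_tail(k, w, p)``, bit-identical.

    Rows are materialised lazily up to ``w_max`` and shared with the direct
    call through the same cache.
    """
    if w_max < 1:
        raise ValueError("w_max must be >= 1")
    if not 0 < p < 1:
        raise ValueError(f"degenerate null: p={p!r}")

    def evaluate(k: int, w: int) -> float:
        _check(k, w, p)
        return float(_tail_row(w, p)[k])

    return evaluate


def tail_row(w: int, p: float) -> np.ndarray:
    """Vector of log10 tails for all counts 0..w at fixed (w, p)."""
    if not 0 < p < 1:
        raise ValueError(f"degenerate null: p={p!r}")
    if w < 0:
        raise ValueError("w must be >= 0")
    return _tail_row(w, p)


def tails_at(k: np.ndarray, w, p: float) -> np.ndarray:
    """Vectorised log10 tails; ``w`` may be a scalar or an array like ``k``."""
    k = np.asarray(k, dtype=np.intp)
    if np.ndim(w) == 0:
        return _tail_row(int(w), p)[k]
    w = np.asarray(w, dtype=np.intp)
    out = np.empty(k.shape, dtype=np.float64)
    for u in np.unique(w):
        mask = w == u
        out[mask] = _tail_row(int(u), p)[k[mask]]
    return out
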
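"""Independent brute-force oracles used to validate the fast implementations.

These deliberately mirror the printed definitions term by term and stay
free of the vectorized/compiled code paths they check.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def lz76_brute(seq) -> int:
    """Exhaustive-history LZ76 phrase count by direct substring search.

    Each phrase is the shortest extension s[m:m+l] that does NOT occur as a
    contiguous substring of s[0:m+l-1]; a trailing reproducible phrase still
    counts as one phrase.
    """
    s = list(seq)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")

    def occurs(sub, prefix):
        k = len(sub)
        return any(prefix[p:p + k] == sub for p in range(len(prefix) - k + 1))

    count = 0
    m = 0
    while m < n:
        l = 1
        while m + l <= n and occurs(s[m:m + l], s[:m + l - 1]):
            l += 1
        count += 1
        m += l
    return count


def wpli_dpli_brute(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """wPLI and dPLI of two analytic sample sequences by direct summation.

    wPLI = |E{Im C}| / E{|Im C|} with C_t = x_t * conj(y_t);
    dPLI = (1/N) Σ H(Δφ_t) with Δφ wrapped to (−π, π], H(0) = 0.5.
    """
    n = len(x)
    imags = [complex(x[t]) * complex(y[t]).conjugate() for t in range(n)]
    imags = [c.imag for c in imags]
    num = abs(sum(imags) / n)
    den = sum(abs(v) for v in imags) / n
    wpli = 0.0 if den == 0 else num / den

    total = 0.0
    for t in range(n):
        dphi = cmath.phase(complex(x[t])) - cmath.phase(complex(y[t]))
        while dphi <= -math.pi:
            dphi += 2 * math.pi
        while dphi > math.pi:
            dphi -= 2 * math.pi
        if dphi > 0:
            total += 1.0
        elif dphi == 0:
            total += 0.5
    return wpli, total / n
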
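"""Numba kernel for the dynamic-time-warping dynamic program.

Full unconstrained DTW with absolute-difference local cost and the
standard {match, insert, delete} step set, using a two-row table so the
memory cost is O(min over a row) rather than O(n*m).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False, error_model="numpy")
def dtw_kernel(a: np.ndarray, b: np.ndarray) -> float:
    n = a.shape[0]
    m = b.shape[0]
    prev = np.empty(m + 1, dtype=np.float64)
    curr = np.empty(m + 1, dtype=np.float64)
    prev[0] = 0.0
    for j in range(1, m + 1):
        prev[j] = np.inf
    for i in range(1, n + 1):
        curr[0] = np.inf
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = abs(ai - b[j - 1])
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = cost + best
        prev, curr = curr, prev
    return prev[m]
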
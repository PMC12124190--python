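"""Affine-gap global alignment kernel over a precomputed score matrix.

The progressive aligner reduces every merge step to a global alignment of two
column-index sequences under a dense column-vs-column score matrix; the
three-state Gotoh recurrence with traceback lives here, JIT-compiled with
numba so desk-scale families align in milliseconds.

Gap cost convention: a gap of length k costs open + (k-1) * extend.
Terminal gaps are charged like internal ones.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e30
# traceback states
_M, _IX, _IY = 0, 1, 2


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG)
    Ix = np.full((la + 1, lb + 1), _NEG)  # gap in B (consumes A rows)
    Iy = np.full((la + 1, lb + 1), _NEG)  # gap in A (consumes B cols)
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
        tb_x[i, 0] = _IX
    for j in range(1, lb + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
        tb_y[0, j] = _IY
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # Ix: A[i-1] against a gap
            o = M[i - 1, j] - gap_open
            e = Ix[i - 1, j] - gap_extend
            if o >= e:
                Ix[i, j] = o
                tb_x[i, j] = _M
            else:
                Ix[i, j] = e
                tb_x[i, j] = _IX
            # Iy: B[j-1] against a gap
            o = M[i, j - 1] - gap_open
            e = Iy[i, j - 1] - gap_extend
            if o >= e:
                Iy[i, j] = o
                tb_y[i, j] = _M
            else:
                Iy[i, j] = e
                tb_y[i, j] = _IY
            # M: A[i-1] paired with B[j-1]
            best = M[i - 1, j - 1]
            state = _M
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                state = _IX
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                state = _IY
            M[i, j] = best + S[i - 1, j - 1]
            tb_m[i, j] = state
    return M, Ix, Iy, tb_m, tb_x, tb_y


def gotoh_global(S: np.ndarray, gap_open: float, gap_extend: float):
    """Globally align index sequences 0..la-1 and 0..lb-1 under score matrix S.

    Returns ``(score, path)`` where ``path`` is a list of ``(i, j)`` pairs with
    ``-1`` marking a gap on that side. Ties prefer match, then a gap in the
    second sequence, for determinism.
    """
    la, lb = S.shape
    if la == 0 or lb == 0:
        path = [(i, -1) for i in range(la)] + [(-1, j) for j in range(lb)]
        gap = 0.0 if (la == 0 and lb == 0) else -(gap_open + (max(la, lb) - 1) * gap_extend)
        return gap, path
    M, Ix, Iy, tb_m, tb_x, tb_y = _gotoh_fill(
        np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_extend)
    )
    i, j = la, lb
    state = _M
    score = M[i, j]
    if Ix[i, j] > score:
        score, state = Ix[i, j], _IX
    if Iy[i, j] > score:
        score, state = Iy[i, j], _IY
    rev: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == _M:
            prev = tb_m[i, j]
            rev.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _IX:
            prev = tb_x[i, j]
            rev.append((i - 1, -1))
            i -= 1
        else:
            prev = tb_y[i, j]
            rev.append((-1, j - 1))
            j -= 1
        state = prev
    rev.reverse()
    return float(score), rev
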
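"""Classic unconstrained dynamic time warping with squared-difference cost.

Given sequences X (length n) and Y (length m), the pointwise cost is

    D[i, j] = (x_i - y_j)**2

(the printed formula; note this is the squared difference, despite the
"Euclidean distance" name sometimes attached to it).  The cumulative matrix
follows the standard recursion

    C[i, j] = D[i, j] + min(C[i-1, j], C[i, j-1], C[i-1, j-1])

with C[0, 0] = D[0, 0] and first row/column accumulating along their only
admissible predecessor.  The DTW distance is C[n-1, m-1]; the optimal path
is recovered by backtracking the argmin predecessor.  No warping window and
no step weights are applied.  Indices in :class:`DtwResult` paths are
0-based (the equivalent textbook convention numbers them from (1, 1)).

The distance is length-normalized as ``DTW / (2 n)`` for equal-length
sequences; for unequal lengths ``DTW / (n + m)`` is used, which degenerates
to the former when n == m.

A deliberately naive exhaustive path-enumeration oracle
(:func:`brute_force_dtw`) is provided for testing; it shares nothing with
the dynamic-programming implementation beyond the cost definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .errors import ValidationError

__all__ = [
    "DtwResult",
    "cost_matrix",
    "cumulative_matrix",
    "dtw_distance",
    "normalize_distance",
    "brute_force_dtw",
    "dump_matrices",
]


@dataclass
class DtwResult:
    """Outcome of one DTW comparison.

    ``distance`` is in squared-amplitude units; ``norm_distance`` is the
    length-normalized distance; ``path`` is a (k, 2) integer array of
    0-based (a_i, b_i) index pairs from (0, 0) to (n-1, m-1), or ``None``
    when only the distance was requested.
    """

    distance: float
    norm_distance: float
    path: np.ndarray | None
    n: int
    m: int


def _as_sequence(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "samples", x), dtype=np.float64).ravel()
    if arr.size < 1:
        raise ValidationError("DTW requires non-empty sequences")
    return arr


def cost_matrix(x, y) -> np.ndarray:
    """Pointwise squared-difference cost matrix, shape (n, m)."""
    xv = _as_sequence(x)
    yv = _as_sequence(y)
    return np.subtract.outer(xv, yv) ** 2


@njit(cache=True)
def _accumulate(d):
    n, m = d.shape
    c = np.empty((n, m))
    c[0, 0] = d[0, 0]
    for j in range(1, m):
        c[0, j] = c[0, j - 1] + d[0, j]
    for i in range(1, n):
        c[i, 0] = c[i - 1, 0] + d[i, 0]
        for j in range(1, m):
            best = c[i - 1, j - 1]
            if c[i - 1, j] < best:
                best = c[i - 1, j]
            if c[i, j - 1] < best:
                best = c[i, j - 1]
            c[i, j] = d[i, j] + best
    return c


@njit(cache=True)
def _distance_only(x, y):
    # Two-row rolling DP: O(m) memory, used for long epochs where the full
    # cumulative matrix (and path) is not needed.
    n = x.shape[0]
    m = y.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    acc = 0.0
    for j in range(m):
        acc += (x[0] - y[j]) ** 2
        prev[j] = acc
    for i in range(1, n):
        curr[0] = prev[0] + (x[i] - y[0]) ** 2
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = (x[i] - y[j]) ** 2 + best
        prev, curr = curr, prev
    return prev[m - 1]


def cumulative_matrix(d: np.ndarray) -> np.ndarray:
    """Cumulative minimum-cost matrix from a cost matrix."""
    d = np.ascontiguousarray(d, dtype=np.float64)
    if d.ndim != 2 or d.size == 0:
        raise ValidationError("cost matrix must be a non-empty 2-D array")
    return _accumulate(d)


def _backtrace(c: np.ndarray) -> np.ndarray:
    """Argmin-predecessor backtrace; ties prefer diagonal, then up, then left."""
    n, m = c.shape
    i, j = n - 1, m - 1
    rev = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, up, left = c[i - 1, j - 1], c[i - 1, j], c[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        rev.append((i, j))
    return np.array(rev[::-1], dtype=np.intp)


def _normalized(distance: float, n: int, m: int) -> float:
    return distance / (2 * n) if n == m else distance / (n + m)


def dtw_distance(x, y, return_path: bool = True) -> DtwResult:
    """Full DTW comparison of two sequences.

    With ``return_path=False`` only the distance is computed, in O(m)
    memory — preferred for long epochs (an 8000-sample pair needs a
    half-gigabyte cumulative matrix otherwise).
    """
    xv = _as_sequence(x)
    yv = _as_sequence(y)
    n, m = xv.size, yv.size
    if return_path:
        c = _accumulate(np.subtract.outer(xv, yv) ** 2)
        distance = float(c[-1, -1])
        path = _backtrace(c)
    else:
        distance = float(_distance_only(xv, yv))
        path = None
    return DtwResult(distance=distance, norm_distance=_normalized(distance, n, m),
                     path=path, n=n, m=m)


def normalize_distance(r: DtwResult) -> float:
    """Length-normalized DTW distance: DTW/(2n) if n == m else DTW/(n+m)."""
    return _normalized(r.distance, r.n, r.m)


_BRUTE_FORCE_LIMIT = 20


def brute_force_dtw(x, y) -> float:
    """Exhaustive enumeration of every monotone alignment path (test oracle).

    Exponential in n+m; guarded at n + m <= 20.  Use :func:`dtw_distance`
    for anything larger.
    """
    xv = _as_sequence(x)
    yv = _as_sequence(y)
    n, m = xv.size, yv.size
    if n + m > _BRUTE_FORCE_LIMIT:
        raise ValidationError(
            f"brute_force_dtw is limited to n + m <= {_BRUTE_FORCE_LIMIT}; "
            "use dtw_distance instead"
        )
    d = (np.subtract.outer(xv, yv) ** 2).tolist()
    best = np.inf
    stack = [(0, 0, d[0][0])]
    while stack:
        i, j, acc = stack.pop()
        if i == n - 1 and j == m - 1:
            if acc < best:
                best = acc
            continue
        if i + 1 < n:
            stack.append((i + 1, j, acc + d[i + 1][j]))
        if j + 1 < m:
            stack.append((i, j + 1, acc + d[i][j + 1]))
        if i + 1 < n and j + 1 < m:
            stack.append((i + 1, j + 1, acc + d[i + 1][j + 1]))
    return float(best)


def dump_matrices(x, y, prefix) -> None:
    """Debug helper: write D, C and the optimal path as delimited text."""
    prefix = Path(prefix)
    d = cost_matrix(x, y)
    c = cumulative_matrix(d)
    r = dtw_distance(x, y, return_path=True)
    np.savetxt(prefix.with_suffix(".cost.csv"), d, fmt="%.17g", delimiter=",")
    np.savetxt(prefix.with_suffix(".cumulative.csv"), c, fmt="%.17g", delimiter=",")
    np.savetxt(prefix.with_suffix(".path.csv"), r.path, fmt="%d", delimiter=",")
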
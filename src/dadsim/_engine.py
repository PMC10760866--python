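"""Column-local stochastic transfer of lattice entries to two daughters.

The replication step moves every non-empty entry of each parent column into
the same column of one of two daughter lattices.  Within a column the
entries are processed in a uniformly random order; each samples a daughter
(probability 1/2 each) and a destination row from its source row's
transfer-kernel distribution, resampling on collision with an
already-placed entry.  After ``MAX_REJECTIONS`` failed draws the entry is
placed uniformly on one of the remaining empty sites of the column -- with
2R sites available for at most R entries this always terminates.

The hot loop is JIT-compiled with numba when available; the pure-Python
body is identical (same RNG call sequence), so results are bit-for-bit
reproducible either way.
"""

from __future__ import annotations

import numpy as np

MAX_REJECTIONS = 100

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _transfer_columns(grid, cdf, out1, out2, rng):
    """Fill ``out1``/``out2`` (pre-zeroed R x N int arrays) in place.

    ``cdf`` is the row-wise cumulative transfer distribution, shape (R, R),
    with cdf[i, -1] == 1.0 exactly.
    """
    n_rows, n_cols = grid.shape
    occ = np.zeros(2 * n_rows, dtype=np.bool_)
    rows = np.empty(n_rows, dtype=np.int64)
    for j in range(n_cols):
        n = 0
        for i in range(n_rows):
            if grid[i, j] != 0:
                rows[n] = i
                n += 1
        if n == 0:
            continue
        # Fisher-Yates: uniformly random processing order within the column.
        for k in range(n - 1, 0, -1):
            m = rng.integers(0, k + 1)
            tmp = rows[k]
            rows[k] = rows[m]
            rows[m] = tmp
        occ[:] = False
        for k in range(n):
            i = rows[k]
            state = grid[i, j]
            site = -1
            for _ in range(MAX_REJECTIONS):
                d = rng.integers(0, 2)
                u = rng.random()
                t = np.searchsorted(cdf[i], u, side="right")
                if t >= n_rows:
                    t = n_rows - 1
                s = d * n_rows + t
                if not occ[s]:
                    site = s
                    break
            if site < 0:
                # Uniform over the remaining empty sites of this column.
                n_free = 0
                for s in range(2 * n_rows):
                    if not occ[s]:
                        n_free += 1
                pick = rng.integers(0, n_free)
                c = 0
                for s in range(2 * n_rows):
                    if not occ[s]:
                        if c == pick:
                            site = s
                            break
                        c += 1
            occ[site] = True
            t = site % n_rows
            if site < n_rows:
                out1[t, j] = state
            else:
                out2[t, j] = state


def transfer_columns(grid: np.ndarray, kernel_cdf: np.ndarray,
                     rng: np.random.Generator):
    """Distribute the entries of ``grid`` into two daughter arrays.

    Returns ``(daughter1, daughter2)``; per column, the multiset of
    non-zero entries of the two daughters equals the parent's.
    """
    out1 = np.zeros_like(grid)
    out2 = np.zeros_like(grid)
    _transfer_columns(grid, kernel_cdf, out1, out2, rng)
    return out1, out2
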
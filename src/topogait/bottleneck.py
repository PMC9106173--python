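"""Exact bottleneck distance between persistence barcodes.

The bottleneck distance is the optimal-transport-style distance

    d(B, B') = inf over bijections gamma of  sup_b ||b - gamma(b)||_inf,

where both barcodes are augmented with zero-length diagonal bars (x, x) so
a bijection always exists. Bars with infinite death can only be matched to
each other, so barcodes with different infinite-bar counts are at infinite
distance (trimmed barcodes never are: trimming removes the infinite bar).

The solver is exact and combinatorial: the optimum is always one of the
candidate values {all pairwise bar distances} ∪ {all diagonal gaps}; a
binary search over the sorted candidates finds the smallest radius r at
which the threshold graph (edges of cost <= r) admits a perfect matching,
decided by maximum bipartite matching. Barcodes here have at most a few
hundred bars, so exactness is cheap.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .persistence import Bar, Barcode
from .signal import InvalidInputError

__all__ = [
    "bar_distance",
    "diagonal_gap",
    "bottleneck_distance",
    "distance_matrix",
]

#: Feasibility slack guarding against representation error at the optimum.
_FEAS_EPS = 1e-12


def bar_distance(b: Bar, b2: Bar) -> float:
    """Infinity-norm distance between two bars.

    Both deaths infinite -> |birth - birth'|; exactly one infinite ->
    +infinity; both finite -> max(|Δbirth|, |Δdeath|).
    """
    if b.is_infinite and b2.is_infinite:
        return abs(b.birth - b2.birth)
    if b.is_infinite or b2.is_infinite:
        return math.inf
    return max(abs(b.birth - b2.birth), abs(b.death - b2.death))


def diagonal_gap(b: Bar) -> float:
    """Distance from a bar to its nearest zero-length (diagonal) bar.

    (death - birth) / 2 for finite bars; infinite bars cannot die to the
    diagonal.
    """
    if b.is_infinite:
        return math.inf
    return (b.death - b.birth) / 2.0


def _finite_arrays(b: Barcode) -> np.ndarray:
    bars = b.finite_bars
    if not bars:
        return np.empty((0, 2))
    return np.array([[bar.birth, bar.death] for bar in bars], dtype=float)


def _feasible(r: float, pair_d: np.ndarray, gaps1: np.ndarray, gaps2: np.ndarray) -> bool:
    """Is there a perfect augmented matching with all costs <= r?"""
    m1, m2 = pair_d.shape
    n = m1 + m2
    thr = r + _FEAS_EPS
    adj = np.ones((n, n), dtype=bool)
    adj[:m1, :m2] = pair_d <= thr
    adj[:m1, m2:] = (gaps1 <= thr)[:, None]
    adj[m1:, :m2] = (gaps2 <= thr)[None, :]
    match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return bool((match != -1).all())


def bottleneck_distance(B: Barcode, B2: Barcode) -> float:
    """Exact bottleneck distance between two barcodes (either may be empty).

    Infinite bars are matched among themselves by sorted births (optimal for
    points on a line); the finite parts are matched through diagonal
    augmentation. Returns +infinity iff the infinite-bar counts differ.
    """
    inf1 = sorted(bar.birth for bar in B.infinite_bars)
    inf2 = sorted(bar.birth for bar in B2.infinite_bars)
    if len(inf1) != len(inf2):
        return math.inf
    cost_inf = max((abs(a - b) for a, b in zip(inf1, inf2)), default=0.0)

    f1 = _finite_arrays(B)
    f2 = _finite_arrays(B2)
    m1, m2 = f1.shape[0], f2.shape[0]
    if m1 == 0 and m2 == 0:
        return cost_inf
    pair_d = np.maximum(
        np.abs(f1[:, :1] - f2[:, 0][None, :]),
        np.abs(f1[:, 1:2] - f2[:, 1][None, :]),
    )
    gaps1 = (f1[:, 1] - f1[:, 0]) / 2.0
    gaps2 = (f2[:, 1] - f2[:, 0]) / 2.0

    cands = np.unique(np.concatenate([pair_d.ravel(), gaps1, gaps2]))
    # the finite-part optimum is the smallest feasible candidate
    lo, hi = 0, cands.size - 1
    if not _feasible(cands[hi], pair_d, gaps1, gaps2):  # pragma: no cover
        raise AssertionError("largest candidate must be feasible")
    while lo < hi:
        mid = (lo + hi) // 2
        if _feasible(cands[mid], pair_d, gaps1, gaps2):
            hi = mid
        else:
            lo = mid + 1
    return max(cost_inf, float(cands[lo]))


def _digest(barcodes: Sequence[Barcode], trial_ids: Sequence[str]) -> str:
    h = hashlib.sha256()
    for tid, bc in zip(trial_ids, barcodes):
        h.update(tid.encode())
        h.update(np.ascontiguousarray(bc.as_array()).tobytes())
    return h.hexdigest()[:16]


def distance_matrix(
    barcodes: Sequence[Barcode],
    trial_ids: Optional[Sequence[str]] = None,
    cache_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """All pairwise bottleneck distances, as a symmetric DataFrame.

    Index and columns are the trial ids. Entries are finite whenever all
    barcodes carry the same number of infinite bars; any infinite entry
    triggers a warning naming the offending pair. When ``cache_dir`` is
    given the matrix is cached on disk keyed by a digest of the inputs.
    """
    n = len(barcodes)
    if n < 2:
        raise InvalidInputError("need at least 2 barcodes")
    if trial_ids is None:
        trial_ids = [str(i) for i in range(n)]
    if len(set(trial_ids)) != n:
        raise InvalidInputError("trial_ids must be unique")

    cache_path = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_path = cache_dir / f"bottleneck_{_digest(barcodes, trial_ids)}.csv"
        if cache_path.exists():
            cached = pd.read_csv(cache_path, index_col=0, float_precision="round_trip")
            cached.index = cached.index.astype(str)
            return cached

    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = bottleneck_distance(barcodes[i], barcodes[j])
            if math.isinf(d):
                warnings.warn(
                    f"infinite bottleneck distance between trials "
                    f"{trial_ids[i]!r} and {trial_ids[j]!r} "
                    f"(different infinite-bar counts)"
                )
            dm[i, j] = dm[j, i] = d
    out = pd.DataFrame(dm, index=list(trial_ids), columns=list(trial_ids))
    if cache_path is not None:
        out.to_csv(cache_path)
    return out
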
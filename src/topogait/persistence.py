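"""Sublevel-set persistence barcodes of 1D signals.

The sublevel set of a signal f at level alpha is {t : f(t) <= alpha}. As
alpha sweeps upward, connected components of the sublevel set are born at
local minima and merge at local maxima; when two components merge, the
younger one (the one born at the higher minimum) dies — the elder rule. The
multiset of (birth, death) level pairs is the 0-dimensional persistence
barcode. Exactly one component never dies: the one born at the global
minimum, recorded as a bar with infinite death.

For a gait trial the barcode reads as an oscillation summary: each gait
cycle contributes one long bar (the pre-toe-off dip paired with the swing
plateau) and one medium bar (the post-heel-strike dip paired with the
foot-flat plateau); the remaining short bars are oscillations, irregular
movements or noise. Removing the k longest bars (k = step count) leaves
exactly that oscillation signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, List, Sequence

import numpy as np

from .signal import InvalidInputError, TimeSeries

__all__ = [
    "Bar",
    "Barcode",
    "Extremum",
    "ExtremaSequence",
    "find_extrema",
    "sublevel_barcode",
    "trim_barcode",
]

INF = math.inf


@dataclass(frozen=True, order=True)
class Bar:
    """One bar: the (birth, death) levels of a sublevel-set component.

    Levels are in signal units (deg/s), never normalised. ``death`` is
    ``math.inf`` for the component born at the global minimum.
    ``birth_index`` is the time index of the minimum that created the
    component (used only as a deterministic tie-break).
    """

    birth: float
    death: float
    birth_index: int = field(default=-1, compare=False)

    def __post_init__(self) -> None:
        if math.isinf(self.birth):
            raise InvalidInputError("bar birth must be finite")
        if not self.birth < self.death:
            raise InvalidInputError(
                f"bar birth must be below death, got ({self.birth}, {self.death})"
            )

    @property
    def length(self) -> float:
        return self.death - self.birth

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.death)


class Barcode:
    """A multiset of bars (duplicates allowed).

    A barcode freshly built from a signal has exactly one infinite bar; a
    trimmed barcode may have none.
    """

    def __init__(self, bars: Iterable[Bar] = ()):
        self.bars: List[Bar] = list(bars)

    def __len__(self) -> int:
        return len(self.bars)

    def __iter__(self) -> Iterator[Bar]:
        return iter(self.bars)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Barcode):
            return NotImplemented
        return sorted((b.birth, b.death) for b in self.bars) == sorted(
            (b.birth, b.death) for b in other.bars
        )

    def __repr__(self) -> str:
        pairs = ", ".join(f"({b.birth:g}, {b.death:g})" for b in self.bars)
        return f"Barcode([{pairs}])"

    @property
    def n_infinite(self) -> int:
        return sum(b.is_infinite for b in self.bars)

    @property
    def finite_bars(self) -> List[Bar]:
        return [b for b in self.bars if not b.is_infinite]

    @property
    def infinite_bars(self) -> List[Bar]:
        return [b for b in self.bars if b.is_infinite]

    def as_array(self) -> np.ndarray:
        """(n, 2) array of (birth, death); infinite deaths become np.inf."""
        if not self.bars:
            return np.empty((0, 2))
        return np.array([[b.birth, b.death] for b in self.bars], dtype=float)


@dataclass(frozen=True)
class Extremum:
    index: int          # first index of the (collapsed) run, original coords
    value: float
    kind: str           # "min" or "max"
    boundary: bool = False


@dataclass(frozen=True)
class ExtremaSequence:
    """Alternating local extrema of a signal after plateau collapsing.

    Runs of equal consecutive samples are collapsed to a single extremum at
    the run's first index, so kinds strictly alternate. Boundary extrema are
    flagged: boundary maxima never kill components in the sweep, boundary
    minima do create them.
    """

    extrema: tuple

    def __iter__(self) -> Iterator[Extremum]:
        return iter(self.extrema)

    def __len__(self) -> int:
        return len(self.extrema)

    @property
    def minima(self) -> List[Extremum]:
        return [e for e in self.extrema if e.kind == "min"]

    @property
    def maxima(self) -> List[Extremum]:
        return [e for e in self.extrema if e.kind == "max"]


def _collapse_runs(values: np.ndarray) -> tuple:
    """Collapse runs of equal consecutive samples.

    Returns (run_values, run_first_index) — one entry per run, with strictly
    different consecutive values.
    """
    keep = np.empty(values.size, dtype=bool)
    keep[0] = True
    np.not_equal(values[1:], values[:-1], out=keep[1:])
    idx = np.flatnonzero(keep)
    return values[idx], idx


def find_extrema(ts: TimeSeries) -> ExtremaSequence:
    """Locate the local extrema of a signal, plateau-collapsed.

    Interior runs that are strictly between their neighbours (monotone
    passage) are not extrema. The first and last runs are always extrema of
    the appropriate kind and carry ``boundary=True``; downstream, boundary
    maxima are ignored as component killers. A constant signal yields a
    single (degenerate) minimum.
    """
    values = np.asarray(ts.values, dtype=float)
    if values.size < 2:
        raise InvalidInputError(
            f"signal {ts.trial_id!r} needs at least 2 samples, got {values.size}"
        )
    rv, ri = _collapse_runs(values)
    n = rv.size
    if n == 1:  # constant signal
        return ExtremaSequence((Extremum(int(ri[0]), float(rv[0]), "min", True),))

    out: List[Extremum] = []
    out.append(
        Extremum(int(ri[0]), float(rv[0]), "min" if rv[0] < rv[1] else "max", True)
    )
    for j in range(1, n - 1):
        v, vl, vr = rv[j], rv[j - 1], rv[j + 1]
        if v < vl and v < vr:
            out.append(Extremum(int(ri[j]), float(v), "min"))
        elif v > vl and v > vr:
            out.append(Extremum(int(ri[j]), float(v), "max"))
    out.append(
        Extremum(
            int(ri[n - 1]), float(rv[n - 1]), "min" if rv[n - 1] < rv[n - 2] else "max", True
        )
    )
    return ExtremaSequence(tuple(out))


def sublevel_barcode(ts: TimeSeries) -> Barcode:
    """Compute the 0-dimensional sublevel-set persistence barcode.

    Implemented as a union-find sweep over the plateau-collapsed samples
    sorted by value (ties broken by time index): each sample joins the
    components of its already-processed neighbours; when a sample bridges
    two components, the younger dies at that sample's level (elder rule;
    equal births resolved in favour of the earlier time index). The
    surviving component is the infinite bar, born at the global minimum.

    The number of finite bars equals the number of local minima minus one,
    and exactly one bar is infinite.
    """
    values = np.asarray(ts.values, dtype=float)
    if values.size < 2:
        raise InvalidInputError(
            f"signal {ts.trial_id!r} needs at least 2 samples, got {values.size}"
        )
    rv, ri = _collapse_runs(values)
    n = rv.size

    order = np.lexsort((np.arange(n), rv))  # by value, then by index
    parent = np.full(n, -1, dtype=np.int64)  # -1 = not yet in any component
    # birth value / original time index of each component's root
    birth_val = np.empty(n)
    birth_idx = np.empty(n, dtype=np.int64)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    bars: List[Bar] = []
    for p in order:
        roots = {find(q) for q in (p - 1, p + 1) if 0 <= q < n and parent[q] != -1}
        if not roots:
            # no lower neighbour: p is a local minimum, a component is born
            parent[p] = p
            birth_val[p] = rv[p]
            birth_idx[p] = ri[p]
        elif len(roots) == 1:
            parent[p] = roots.pop()
        else:
            # p is a local maximum bridging two components
            rp, rq = roots
            # elder rule: lower birth survives; tie -> earlier time index
            if (birth_val[rp], birth_idx[rp]) <= (birth_val[rq], birth_idx[rq]):
                elder, young = rp, rq
            else:
                elder, young = rq, rp
            bars.append(
                Bar(float(birth_val[young]), float(rv[p]), int(birth_idx[young]))
            )
            parent[young] = elder
            parent[p] = elder
    gmin = int(order[0])
    bars.append(Bar(float(rv[gmin]), INF, int(ri[gmin])))
    return Barcode(bars)


def trim_barcode(b: Barcode, k: int) -> Barcode:
    """Remove the k longest bars (infinite bars count as longest).

    Length ties are broken deterministically: length descending, then birth
    ascending, then birth time index ascending. ``k`` larger than the
    barcode empties it; the input barcode is left unmodified.
    """
    if k < 0:
        raise InvalidInputError("k must be nonnegative")
    if k == 0:
        return Barcode(list(b.bars))
    ranked = sorted(b.bars, key=lambda bar: (-bar.length, bar.birth, bar.birth_index))
    return Barcode(ranked[k:])
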
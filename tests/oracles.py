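"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: the barcode oracle
recomputes connected components of every sublevel set from scratch, and
the bottleneck oracle enumerates all augmented matchings.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sweep_barcode(values) -> list:
    """0-dim sublevel-set barcode by literal threshold sweeping.

    For each distinct sample value alpha (ascending), recompute the runs of
    the boolean mask {f <= alpha}. A run that contains no previously alive
    component is a birth (at the run's minimum value); a run swallowing
    several components kills all but the eldest at alpha. Returns a list of
    (birth, death) pairs, death = math.inf for the survivor.
    """
    values = np.asarray(values, dtype=float)
    alive = []  # list of (birth_value, birth_index, set_of_indices)
    bars = []
    for alpha in np.unique(values):
        mask = values <= alpha
        runs = []
        start = None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                runs.append(set(range(start, i)))
                start = None
        if start is not None:
            runs.append(set(range(start, mask.size)))
        new_alive = []
        for run in runs:
            members = [c for c in alive if c[2] & run]
            if not members:
                idx = min(run, key=lambda i: (values[i], i))
                new_alive.append((values[idx], idx, run))
            else:
                elder = min(members, key=lambda c: (c[0], c[1]))
                for c in members:
                    if c is not elder:
                        bars.append((c[0], float(alpha)))
                new_alive.append((elder[0], elder[1], run))
        alive = new_alive
    assert len(alive) == 1
    bars.append((alive[0][0], math.inf))
    return sorted(bars)


def _pair_cost(b, b2) -> float:
    (x, y), (x2, y2) = b, b2
    if math.isinf(y) and math.isinf(y2):
        return abs(x - x2)
    if math.isinf(y) or math.isinf(y2):
        return math.inf
    return max(abs(x - x2), abs(y - y2))


def brute_bottleneck(bars1, bars2) -> float:
    """Bottleneck distance by exhaustive enumeration of augmented matchings.

    ``bars1``/``bars2`` are sequences of (birth, death) pairs; death may be
    math.inf. Every subset of each finite part may be matched bijectively,
    the rest dies to the diagonal; infinite bars are enumerated over all
    permutations. Exponential — use only on tiny barcodes.
    """
    inf1 = sorted(x for x, y in bars1 if math.isinf(y))
    inf2 = sorted(x for x, y in bars2 if math.isinf(y))
    if len(inf1) != len(inf2):
        return math.inf
    best_inf = math.inf if inf1 else 0.0
    for perm in itertools.permutations(inf2):
        cost = max((abs(a - b) for a, b in zip(inf1, perm)), default=0.0)
        best_inf = min(best_inf, cost)

    f1 = [(x, y) for x, y in bars1 if not math.isinf(y)]
    f2 = [(x, y) for x, y in bars2 if not math.isinf(y)]
    gap = lambda b: (b[1] - b[0]) / 2.0
    best_fin = math.inf
    for k in range(min(len(f1), len(f2)) + 1):
        for s1 in itertools.combinations(range(len(f1)), k):
            for s2 in itertools.permutations(range(len(f2)), k):
                matched = [_pair_cost(f1[i], f2[j]) for i, j in zip(s1, s2)]
                unmatched = [gap(f1[i]) for i in range(len(f1)) if i not in s1]
                unmatched += [gap(f2[j]) for j in range(len(f2)) if j not in s2]
                cost = max(matched + unmatched, default=0.0)
                best_fin = min(best_fin, cost)
    return max(best_inf, best_fin)
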
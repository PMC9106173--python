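"""Group separability and density features on the embedded point cloud.

Three features are computed for groups of embedded points:

* the pairwise silhouette score Sil(C_i, C_j) — how separable group i is
  from group j (asymmetric; in [-1, 1]);
* the mean squared intra-group distance MSD(C_i) — the mean of the squared
  Euclidean distances over the n(n-1)/2 unordered distinct pairs;
* the squared diameter SD(C_i) — the maximum squared pairwise distance.

MSD and SD are complementary density measures: a group with low MSD but
high SD contains an outlier. All features use the plain Euclidean distance
in the embedded space; groups always come from metadata, never from
clustering the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .embedding import PointCloud
from .signal import InvalidInputError, TrialRecord

__all__ = [
    "Partition",
    "SingletonGroupError",
    "silhouette_point",
    "silhouette_group",
    "msd",
    "sd",
    "experiment_tables",
    "EDSS_THRESHOLDS",
]

#: Severity thresholds used for the {EDSS <= i} vs {EDSS > i} partitions.
EDSS_THRESHOLDS = (0.0, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


class SingletonGroupError(ValueError):
    """A feature needing within-group distances was asked of a singleton."""


@dataclass(frozen=True)
class Partition:
    """A labelled grouping of trial ids (groups disjoint, possibly partial)."""

    groups: Dict[str, tuple]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set = set()
        norm = {}
        for label, ids in self.groups.items():
            ids = tuple(ids)
            if seen & set(ids):
                raise InvalidInputError(f"partition {self.name!r}: groups overlap")
            seen |= set(ids)
            norm[label] = ids
        object.__setattr__(self, "groups", norm)


def silhouette_point(x: np.ndarray, Ci: np.ndarray, Cj: np.ndarray) -> float:
    """Silhouette of one point of group i with respect to group j.

    (b - a) / max(a, b), where a is the mean distance from x to the other
    points of its own group and b the mean distance from x to group j.
    Plain (not squared) Euclidean distances.
    """
    x = np.asarray(x, float)
    Ci = np.atleast_2d(np.asarray(Ci, float))
    Cj = np.atleast_2d(np.asarray(Cj, float))
    if Ci.shape[0] < 2:
        raise SingletonGroupError(
            "within-group mean distance undefined for a singleton group"
        )
    d_own = np.linalg.norm(Ci - x, axis=1)
    # x itself contributes a zero distance; exclude exactly one copy of it
    a = (d_own.sum()) / (Ci.shape[0] - 1)
    b = np.linalg.norm(Cj - x, axis=1).mean()
    denom = max(a, b)
    if denom == 0:
        return 0.0
    return (b - a) / denom


def silhouette_group(Ci: np.ndarray, Cj: np.ndarray) -> float:
    """Mean silhouette of the points of group i with respect to group j.

    Not symmetric: Sil(C_i, C_j) != Sil(C_j, C_i) in general.
    """
    Ci = np.atleast_2d(np.asarray(Ci, float))
    Cj = np.atleast_2d(np.asarray(Cj, float))
    if Ci.shape[0] < 2:
        raise SingletonGroupError(
            "group silhouette undefined for a singleton group"
        )
    if Cj.shape[0] < 1:
        raise InvalidInputError("other group must be non-empty")
    d_within = cdist(Ci, Ci)
    a = d_within.sum(axis=1) / (Ci.shape[0] - 1)
    b = cdist(Ci, Cj).mean(axis=1)
    denom = np.maximum(a, b)
    sil = np.where(denom == 0, 0.0, (b - a) / np.where(denom == 0, 1.0, denom))
    return float(sil.mean())


def msd(Ci: np.ndarray) -> float:
    """Mean squared intra-group distance over unordered distinct pairs."""
    Ci = np.atleast_2d(np.asarray(Ci, float))
    if Ci.shape[0] < 2:
        raise SingletonGroupError("MSD undefined for a singleton group")
    return float(np.mean(pdist(Ci, "sqeuclidean")))


def sd(Ci: np.ndarray) -> float:
    """Squared diameter: maximum squared pairwise distance (0 for singletons)."""
    Ci = np.atleast_2d(np.asarray(Ci, float))
    if Ci.shape[0] < 1:
        raise InvalidInputError("group must be non-empty")
    if Ci.shape[0] == 1:
        return 0.0
    return float(np.max(pdist(Ci, "sqeuclidean")))


def _sil_or_nan(Ci: np.ndarray, Cj: np.ndarray) -> float:
    if Ci.shape[0] < 2 or Cj.shape[0] < 1:
        return float("nan")
    return silhouette_group(Ci, Cj)


def _msd_or_nan(Ci: np.ndarray) -> float:
    return float("nan") if Ci.shape[0] < 2 else msd(Ci)


def _sd_or_nan(Ci: np.ndarray) -> float:
    return float("nan") if Ci.shape[0] < 1 else sd(Ci)


def hs_ms_table(pc: PointCloud, meta: Sequence[TrialRecord]) -> pd.DataFrame:
    """Healthy-vs-patient separability (one row)."""
    ids = {"HS": [], "MS": []}
    for r in meta:
        if r.trial_id in pc.coords.index:
            ids[r.group].append(r.trial_id)
    hs, ms = pc.points(ids["HS"]), pc.points(ids["MS"])
    row = {
        "Sil(HS,MS)": _sil_or_nan(hs, ms),
        "Sil(MS,HS)": _sil_or_nan(ms, hs),
        "MSD(HS)": _msd_or_nan(hs),
        "MSD(MS)": _msd_or_nan(ms),
        "SD(HS)": _sd_or_nan(hs),
        "SD(MS)": _sd_or_nan(ms),
    }
    return pd.DataFrame([row])


def edss_table(
    pc: PointCloud,
    meta: Sequence[TrialRecord],
    thresholds: Sequence[float] = EDSS_THRESHOLDS,
) -> pd.DataFrame:
    """Severity-stratified separability: {EDSS <= i} vs {EDSS > i} per i.

    Healthy subjects carry EDSS 0. Both silhouette orientations are
    reported for every threshold.
    """
    recs = [r for r in meta if r.trial_id in pc.coords.index]
    rows = []
    for thr in thresholds:
        low = [r.trial_id for r in recs if float(r.edss) <= thr]
        high = [r.trial_id for r in recs if float(r.edss) > thr]
        lo, hi = pc.points(low), pc.points(high)
        rows.append({
            "i": thr,
            "Sil(<=i,>i)": _sil_or_nan(lo, hi),
            "Sil(>i,<=i)": _sil_or_nan(hi, lo),
            "MSD(<=i)": _msd_or_nan(lo),
            "MSD(>i)": _msd_or_nan(hi),
            "SD(<=i)": _sd_or_nan(lo),
            "SD(>i)": _sd_or_nan(hi),
        })
    return pd.DataFrame(rows)


def longitudinal_table(pc: PointCloud, meta: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-subject baseline-vs-follow-up comparison.

    One row per subject; silhouettes are computed only for the pair
    (M0_i, M6_i) of that subject's two session groups. A session with a
    single point gets NaN silhouettes/MSD (the silhouette is undefined
    there) but still reports its SD.
    """
    by_subject: Dict[str, Dict[str, List[str]]] = {}
    for r in meta:
        if r.trial_id not in pc.coords.index:
            continue
        by_subject.setdefault(r.subject_id, {"M0": [], "M6": []})
        by_subject[r.subject_id].setdefault(r.session, []).append(r.trial_id)
    rows = []
    for subj in sorted(by_subject):
        m0 = pc.points(by_subject[subj]["M0"])
        m6 = pc.points(by_subject[subj]["M6"])
        rows.append({
            "subject": subj,
            "Sil(M0,M6)": _sil_or_nan(m0, m6),
            "Sil(M6,M0)": _sil_or_nan(m6, m0),
            "MSD(M0)": _msd_or_nan(m0),
            "MSD(M6)": _msd_or_nan(m6),
            "SD(M0)": _sd_or_nan(m0),
            "SD(M6)": _sd_or_nan(m6),
        })
    return pd.DataFrame(rows)


def experiment_tables(
    pc: PointCloud,
    meta: Sequence[TrialRecord],
    experiments: Sequence[str] = ("HS_MS", "EDSS", "longitudinal"),
) -> Dict[str, pd.DataFrame]:
    """The three cohort experiments: HS/MS, EDSS thresholds, longitudinal."""
    known = {
        "HS_MS": hs_ms_table,
        "EDSS": edss_table,
        "longitudinal": longitudinal_table,
    }
    out = {}
    for name in experiments:
        if name not in known:
            raise InvalidInputError(f"unknown experiment {name!r}")
        out[name] = known[name](pc, meta)
    return out
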
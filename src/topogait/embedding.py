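"""UMAP projection of the bottleneck metric space to 2D/3D.

Barcodes with the bottleneck distance form a non-Euclidean metric space;
UMAP with a precomputed dissimilarity embeds it into the plane while
preserving neighbourhood structure. Absolute coordinates of the embedding
carry no meaning — only relative positions and neighbourhood relations do —
and the algorithm is stochastic, so the seed is mandatory (default 0) and
recorded in all outputs.

Defaults follow the cohort analysis this package implements:
n_neighbors = 45 (favouring global structure), min_dist = 0.3, 2
components. n_neighbors is silently capped at n - 1 for small cohorts
(with a logged warning).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .signal import InvalidInputError

__all__ = ["EmbedConfig", "PointCloud", "embed"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbedConfig:
    n_neighbors: int = 45
    min_dist: float = 0.3
    n_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise InvalidInputError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise InvalidInputError("min_dist must be >= 0")
        if self.n_components not in (2, 3):
            raise InvalidInputError("n_components must be 2 or 3")


@dataclass(frozen=True)
class PointCloud:
    """Embedded coordinates, one point per trial, in input order."""

    coords: pd.DataFrame  # index = trial_id, columns = x, y[, z]
    config: EmbedConfig = field(default_factory=EmbedConfig)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords.to_numpy())):
            raise InvalidInputError("embedded coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    def points(self, trial_ids: Sequence[str]) -> np.ndarray:
        return self.coords.loc[list(trial_ids)].to_numpy()


def _validate_dm(dm: pd.DataFrame) -> np.ndarray:
    arr = dm.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InvalidInputError("distance matrix must be square")
    if np.isnan(arr).any():
        raise InvalidInputError("distance matrix contains NaN")
    if not np.isfinite(arr).all():
        raise InvalidInputError("distance matrix contains infinite entries")
    if (arr < 0).any():
        raise InvalidInputError("distance matrix has negative entries")
    if not np.allclose(arr, arr.T, rtol=0, atol=1e-9):
        raise InvalidInputError("distance matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0, atol=1e-9):
        raise InvalidInputError("distance matrix diagonal is not zero")
    return arr


def embed(dm: pd.DataFrame, cfg: EmbedConfig = EmbedConfig()) -> PointCloud:
    """Embed a precomputed distance matrix with UMAP.

    Deterministic for a fixed ``cfg.seed`` (repeated calls are
    bit-identical). The dissimilarity is passed to UMAP as a precomputed
    metric and never recomputed from coordinates. Output rows align with
    the distance matrix's trial-id order.
    """
    import umap  # deferred: first import triggers numba compilation

    arr = _validate_dm(dm)
    n = arr.shape[0]
    if n < 4:
        raise InvalidInputError(f"need at least 4 trials to embed, got {n}")
    n_neighbors = cfg.n_neighbors
    if n_neighbors >= n:
        n_neighbors = n - 1
        logger.warning(
            "n_neighbors=%d exceeds cohort size %d; capped at %d",
            cfg.n_neighbors, n, n_neighbors,
        )
    with warnings.catch_warnings():
        # umap warns about precomputed metrics and forced determinism
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            metric="precomputed",
            n_neighbors=n_neighbors,
            min_dist=cfg.min_dist,
            n_components=cfg.n_components,
            random_state=cfg.seed,
        )
        coords = reducer.fit_transform(arr)
    cols = ["x", "y", "z"][: cfg.n_components]
    frame = pd.DataFrame(coords.astype(float), index=dm.index, columns=cols)
    frame.index.name = "trial_id"
    return PointCloud(coords=frame, config=cfg)
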
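"""Spatial label reprogramming: neighborhood plurality-vote relabeling.

Spectral-only classification misfires at component edges, where the laser
footprint straddles the target silhouette and the recorded spectrum is
attenuated and flattened.  Geometry repairs this: each scan point is
revisited and assigned the plurality class of its N spatially nearest
neighbors (Euclidean distance, default N = 12).  In the default
``sequential`` mode labels are rewritten in place as the single pass
proceeds, so later points vote with already-corrected labels; ``frozen``
mode votes with the input labels only and is order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ReprogramConfig",
    "NeighborIndex",
    "pairwise_distances",
    "nearest_neighbors",
    "reprogram_labels",
]

#: Above this point count, neighbor lists come from a KD-tree instead of
#: the dense distance matrix; results are identical up to distance ties.
DENSE_CAP_DEFAULT = 4000


@dataclass
class ReprogramConfig:
    """Settings of the relabeling pass.

    Parameters
    ----------
    n_neighbors : int
        Neighborhood size N (empirically best at 12 for canopy-density
        scans; exposed, not hard-coded).
    update_mode : {"sequential", "frozen"}
        Whether votes use labels as already rewritten during the pass or
        the input labels throughout.
    tie_break : {"keep_current", "nearest_class"}
        On a tied plurality: keep the point's current label when it is
        among the tied classes, else (or always, for ``nearest_class``)
        take the tied class of the nearest neighbor.
    order : ndarray or None
        Visit order of the sequential pass; default input order.
    passes : int
        Number of full passes (the method uses one).
    """

    n_neighbors: int = 12
    update_mode: str = "sequential"
    tie_break: str = "keep_current"
    order: np.ndarray | None = None
    passes: int = 1
    dense_cap: int = DENSE_CAP_DEFAULT

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.update_mode not in ("sequential", "frozen"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")
        if self.tie_break not in ("keep_current", "nearest_class"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


@dataclass
class NeighborIndex:
    """Per-point nearest-neighbor lists, ascending by distance.

    ``indices[k]`` holds the ``n_neighbors`` other points closest to point
    k (self excluded); exact distance ties are broken by lower index.
    """

    indices: np.ndarray
    n_neighbors: int


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Dense symmetric Euclidean distance matrix S(i, j)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.size and not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    diff = coords[:, None, :] - coords[None, :, :]
    S = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    np.fill_diagonal(S, 0.0)
    return S


def _neighbors_dense(coords: np.ndarray, n: int) -> np.ndarray:
    """Neighbor lists via chunked dense distances with stable tie-breaks."""
    npts = coords.shape[0]
    out = np.empty((npts, n), dtype=np.int64)
    chunk = max(1, int(2e7) // max(npts, 1))
    for lo in range(0, npts, chunk):
        hi = min(lo + chunk, npts)
        d = np.sqrt(
            ((coords[lo:hi, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        )
        rows = np.arange(lo, hi)
        d[np.arange(hi - lo), rows] = np.inf  # exclude self
        # stable sort on distance => equal distances keep ascending index
        order = np.argsort(d, axis=1, kind="stable")
        out[lo:hi] = order[:, :n]
    return out


def _neighbors_tree(coords: np.ndarray, n: int) -> np.ndarray:
    tree = cKDTree(coords)
    d, idx = tree.query(coords, k=n + 1)
    out = np.empty((coords.shape[0], n), dtype=np.int64)
    for k in range(coords.shape[0]):
        dk, ik = d[k], idx[k]
        keep = ik != k
        dk, ik = dk[keep][:n], ik[keep][:n]
        # normalize tie order to (distance, index) like the dense path
        out[k] = ik[np.lexsort((ik, dk))]
    return out


def nearest_neighbors(
    coords: np.ndarray, n_neighbors: int, dense_cap: int = DENSE_CAP_DEFAULT
) -> NeighborIndex:
    """The ``n_neighbors`` spatially closest other points, per point."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    npts = coords.shape[0]
    if npts < 2:
        raise ValueError("nearest_neighbors needs at least two points")
    if n_neighbors >= npts:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= point count {npts}; using {npts - 1}",
            stacklevel=2,
        )
        n_neighbors = npts - 1
    if npts <= dense_cap:
        idx = _neighbors_dense(coords, n_neighbors)
    else:
        idx = _neighbors_tree(coords, n_neighbors)
    return NeighborIndex(indices=idx, n_neighbors=n_neighbors)


def _vote(
    neigh: np.ndarray,
    labels: np.ndarray,
    current: int,
    tie_break: str,
) -> int:
    """Plurality class among the neighbor labels, with configured tie-break."""
    votes = labels[neigh]
    classes, counts = np.unique(votes, return_counts=True)
    top = classes[counts == counts.max()]
    if len(top) == 1:
        return int(top[0])
    if tie_break == "keep_current" and current in top:
        return int(current)
    top_set = set(int(c) for c in top)
    for j in neigh:  # ascending distance; first neighbor in a tied class
        if int(labels[j]) in top_set:
            return int(labels[j])
    return int(top[0])  # unreachable: top classes come from the votes


def reprogram_labels(
    coords: np.ndarray,
    labels: np.ndarray,
    config: ReprogramConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel every point by its neighborhood plurality class.

    Returns ``(new_labels, changed)`` where ``changed`` marks points whose
    final label differs from the input — the mask used to visualize where
    the spatial constraint rewrote the spectral classification.
    """
    config = config or ReprogramConfig()
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (coords.shape[0],):
        raise ValueError("labels length must equal point count")
    if coords.shape[0] < 2:
        return labels.copy(), np.zeros(coords.shape[0], dtype=bool)

    neigh = nearest_neighbors(coords, config.n_neighbors, config.dense_cap).indices
    order = (
        np.arange(coords.shape[0])
        if config.order is None
        else np.asarray(config.order, dtype=np.int64)
    )
    out = labels.copy()
    for _ in range(config.passes):
        source = out if config.update_mode == "sequential" else out.copy()
        for k in order:
            out[k] = _vote(neigh[k], source, int(out[k]), config.tie_break)
    return out, out != labels
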
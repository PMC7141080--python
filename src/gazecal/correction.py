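"""Gaze correction by inverse-distance weighting of calibration residuals.

Plain IDW (Shepard interpolation) moves an estimated gaze point by the
distance-weighted mean of the correction vectors v_i observed at the
calibration nodes:

    v_p = sum_i v_i / d_i^r  /  sum_i 1 / d_i^r

with d_i the Euclidean distance from the query point to node i and r > 0
(default 2).  The time-windowed variant ("Modified IDW") first finds the
node Np spatially nearest to the query and restricts the sum to nodes
recorded within +-T milliseconds of Np's timestamp (default T = 200 ms),
so only residuals from the same stretch of the calibration sweep are mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ResidualSet
from .exceptions import NoNodes

__all__ = ["CorrectionField", "idw_vector", "select_window", "correct", "correct_many"]


@dataclass
class CorrectionField:
    """Calibration nodes with residual vectors plus the IDW parameters."""

    nodes: ResidualSet
    r: float = 2.0
    window_ms: float = 200.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("IDW power r must be positive")
        if self.window_ms <= 0:
            raise ValueError("time window T must be positive")
        if len(self.nodes) < 1:
            raise NoNodes("correction field needs at least one node")


def idw_vector(field: CorrectionField, p, subset=None) -> np.ndarray:
    """Shepard-interpolated correction vector at point ``p``.

    ``subset`` is an optional boolean mask or index array over the nodes.
    A query coinciding with a node (d = 0) returns that node's vector
    (the mean, if several nodes coincide); the weight 1/d^r is otherwise
    undefined there.
    """
    nodes = field.nodes
    xy = nodes.node_xy
    vec = nodes.vectors
    if subset is not None:
        xy = xy[subset]
        vec = vec[subset]
    if len(xy) == 0:
        raise NoNodes("empty node subset for IDW")
    d = np.hypot(*(xy - np.asarray(p, dtype=float)).T)
    hit = d == 0.0
    if hit.any():
        return vec[hit].mean(axis=0)
    # scale by the nearest distance so the largest weight is exactly 1,
    # keeping 1/d^r finite arbitrarily close to a node
    w = (d.min() / d) ** field.r
    return (w @ vec) / w.sum()


def select_window(field: CorrectionField, p) -> np.ndarray:
    """Boolean mask of nodes inside the time window around the nearest node.

    Np is the node spatially nearest to ``p`` (ties break to the earlier
    timestamp); the window keeps every node e with |t_Np - t_e| <= T,
    closed on both sides.  Np itself is always selected.
    """
    nodes = field.nodes
    d = np.hypot(*(nodes.node_xy - np.asarray(p, dtype=float)).T)
    # among minimal distances, take the earliest timestamp
    minimal = d == d.min()
    t_np = nodes.node_t[minimal].min()
    return np.abs(nodes.node_t - t_np) <= field.window_ms


def correct(field: CorrectionField, p, method: str = "midw") -> np.ndarray:
    """Corrected gaze point: ``p`` plus the IDW vector over the chosen nodes.

    method 'idw' uses all calibration nodes; 'midw' restricts to the time
    window around the spatially nearest node; 'raw' returns ``p`` unchanged.
    """
    p = np.asarray(p, dtype=float)
    if method == "raw":
        return p.copy()
    if method == "idw":
        return p + idw_vector(field, p)
    if method == "midw":
        return p + idw_vector(field, p, subset=select_window(field, p))
    raise ValueError(f"unknown correction method: {method!r}")


def correct_many(field: CorrectionField, points, method: str = "midw") -> np.ndarray:
    """Apply :func:`correct` to an (N, 2) array of points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([correct(field, p, method) for p in pts])
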
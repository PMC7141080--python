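"""Concentric-circle calibration marker detection in world-camera frames.

The marker is a thick black ring containing a white ring which encloses a
smaller filled black disk (a thin white cross on the center is ignored for
localization).  Detection looks for that dark/light/dark nesting in the
binarized frame: a dark component with a hole whose interior contains more
dark pixels, the three regions' centroids agreeing to within 10% of the
outer radius.  The returned center is the innermost disk's centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage import measure

from .exceptions import AmbiguousMarker, NoMarkerFound

__all__ = ["MarkerSample", "detect_marker"]

CONCENTRICITY_TOL = 0.10  # max centroid disagreement as fraction of outer radius
AMBIGUITY_CONFIDENCE = 0.8


@dataclass
class MarkerSample:
    """Detected marker center with a ring-concentricity confidence score."""

    timestamp: int  # ms
    center: tuple[float, float]  # (x, y) world px
    confidence: float  # 1 - max pairwise centroid distance / outer radius


def _centroid(mask: np.ndarray) -> np.ndarray:
    r, c = np.nonzero(mask)
    return np.array([c.mean(), r.mean()])  # (x, y)


def detect_marker(image: np.ndarray, timestamp: int = 0) -> MarkerSample:
    """Find the nested dark-light-dark marker in a grayscale frame.

    Raises NoMarkerFound when no nested triple exists and AmbiguousMarker
    when more than one candidate scores confidence above 0.8.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("detect_marker expects a single-channel image")
    if min(image.shape) < 128:
        raise ValueError("frame too small; min dimension 128 px")

    lo, hi = int(image.min()), int(image.max())
    if lo == hi:
        raise NoMarkerFound("blank frame")
    # midpoint of the dynamic range: the printed marker is black on a light
    # scene, and Otsu degenerates when the marker covers a tiny fraction
    dark = image < (lo + hi) / 2.0
    if not dark.any() or dark.all():
        raise NoMarkerFound("no dark/light structure in frame")

    labels = measure.label(dark, connectivity=2)
    candidates = []
    for region in measure.regionprops(labels):
        ring = labels == region.label
        filled = binary_fill_holes(ring)
        hole = filled & ~ring
        if not hole.any():
            continue  # solid blob, no white interior
        inner_dark = hole & dark  # the filled disk (and any cross remnants)
        inner_white = hole & ~dark
        if not inner_dark.any() or not inner_white.any():
            continue
        outer_radius = np.sqrt(filled.sum() / np.pi)
        c_outer = _centroid(ring)
        c_white = _centroid(inner_white)
        c_inner = _centroid(inner_dark)
        pts = np.array([c_outer, c_white, c_inner])
        dists = [
            np.linalg.norm(pts[i] - pts[j]) for i in range(3) for j in range(i + 1, 3)
        ]
        if max(dists) > CONCENTRICITY_TOL * outer_radius:
            continue
        confidence = 1.0 - max(dists) / outer_radius
        candidates.append((confidence, tuple(c_inner)))

    if not candidates:
        raise NoMarkerFound("no nested dark-light-dark contour triple")
    strong = [c for c in candidates if c[0] > AMBIGUITY_CONFIDENCE]
    if len(strong) > 1:
        raise AmbiguousMarker(
            f"{len(strong)} marker candidates above confidence "
            f"{AMBIGUITY_CONFIDENCE}"
        )
    confidence, center = max(candidates)
    return MarkerSample(
        timestamp=timestamp,
        center=(float(center[0]), float(center[1])),
        confidence=float(confidence),
    )
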
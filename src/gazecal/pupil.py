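"""Dark-pupil detection and the distance-transform uncertainty field.

The detector targets the dark-pupil regime of IR-illuminated eye frames:
the pupil is the darkest sizeable blob.  The threshold is taken from the
lowest spike of the intensity histogram plus a fixed offset, the binarized
frame is cleaned by a 5x5 morphological closing (which also fills specular
glint holes), and the largest dark connected component is kept.  Its contour
is extracted at sub-pixel resolution and an ellipse is fitted to it by
algebraic least squares; the reported center is the ellipse center, which is
more robust to partial occlusion than the pixel centroid.

The uncertainty field expresses where the true center could plausibly be:
inside the detected contour, 1 - DT/max(DT) with DT the Euclidean distance
to the contour, so the value is 1 on the boundary (least certain that the
center is there) and 0 at the deepest interior point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter1d
from skimage import measure, morphology
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

from .exceptions import BorderClippedWarning, DegenerateContour, NoPupilFound

MIN_PUPIL_AREA_PX = 100.0
THRESHOLD_OFFSET = 15

__all__ = [
    "PupilSample",
    "UncertaintyField",
    "detect_pupil",
    "compute_uncertainty_field",
]


@dataclass
class PupilSample:
    """Detected pupil in one eye frame."""

    timestamp: int  # ms
    center: tuple[float, float]  # (u, v) px, ellipse center
    contour: np.ndarray  # (K, 2) closed polygon, (u, v) px
    ellipse_axes: tuple[float, float]  # semi-axes (a, b), a >= b
    ellipse_angle: float  # degrees, major-axis orientation
    area_px: float  # dark component pixel count


@dataclass
class UncertaintyField:
    """Normalized center-location uncertainty over the pupil's bounding box."""

    values: np.ndarray  # float grid, NaN outside the pupil
    mask: np.ndarray  # boolean, True for in-pupil pixels
    origin: tuple[int, int]  # (u0, v0) of the grid in frame coordinates


def _dark_threshold(image: np.ndarray) -> int:
    """Lowest histogram spike plus a fixed offset (dark-pupil heuristic)."""
    hist = np.bincount(image.ravel(), minlength=256).astype(float)
    smooth = gaussian_filter1d(hist, sigma=2.0)
    floor = max(smooth.max() * 1e-3, 1.0)
    for i in range(256):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < 255 else -np.inf
        if smooth[i] >= floor and smooth[i] >= left and smooth[i] >= right:
            return min(255, i + THRESHOLD_OFFSET)
    return THRESHOLD_OFFSET


def detect_pupil(
    image: np.ndarray, timestamp: int = 0, min_area_px: float = MIN_PUPIL_AREA_PX
) -> PupilSample:
    """Locate the dark pupil in a single-channel eye frame.

    Raises NoPupilFound when no dark component reaches ``min_area_px``;
    warns (BorderClippedWarning) when the chosen component touches the frame
    border, but still returns it.  Deterministic.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("detect_pupil expects a single-channel image")
    if min(image.shape) < 64:
        raise ValueError("frame too small; min dimension 64 px")
    if image.dtype != np.uint8:
        image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    thr = _dark_threshold(image)
    mask = image <= thr
    if mask.mean() > 0.5:
        # the dark-pupil premise is a minority dark region; a mostly-dark
        # (or uniform) frame has no pupil to find
        raise NoPupilFound("no distinct dark region in frame")
    # closing fills glint holes and smooths ragged threshold edges
    mask = morphology.closing(mask, np.ones((5, 5), dtype=bool))
    labels = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area_px]
    if not props:
        raise NoPupilFound(
            f"no dark component of area >= {min_area_px} px^2 "
            f"(threshold {thr})"
        )
    region = max(props, key=lambda p: p.area)
    comp = labels == region.label
    if (
        comp[0, :].any()
        or comp[-1, :].any()
        or comp[:, 0].any()
        or comp[:, -1].any()
    ):
        warnings.warn(
            "pupil component touches the frame border", BorderClippedWarning
        )

    contours = measure.find_contours(comp.astype(float), 0.5)
    if not contours:
        raise NoPupilFound("dark component has no traceable contour")
    contour_rc = max(contours, key=len)
    contour_uv = contour_rc[:, ::-1]  # (row, col) -> (u, v)

    ell = measure.EllipseModel.from_estimate(contour_uv)
    if not ell or not np.all(np.isfinite([*ell.center, *ell.axis_lengths])):
        # fall back to the raw-moment centroid and axis-aligned extents
        vc, uc = region.centroid
        h = region.bbox[2] - region.bbox[0]
        w = region.bbox[3] - region.bbox[1]
        a, b = max(w, h) / 2.0, min(w, h) / 2.0
        return PupilSample(timestamp, (uc, vc), contour_uv, (a, b), 0.0, float(region.area))
    (uc, vc), (a, b), theta = ell.center, ell.axis_lengths, ell.theta
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    angle = float(np.rad2deg(theta) % 180.0)
    return PupilSample(
        timestamp=timestamp,
        center=(float(uc), float(vc)),
        contour=contour_uv,
        ellipse_axes=(float(a), float(b)),
        ellipse_angle=angle,
        area_px=float(region.area),
    )


def compute_uncertainty_field(contour: np.ndarray, center=None) -> UncertaintyField:
    """Distance-transform uncertainty of the center location inside a contour.

    ``field(p) = 1 - DT(p)/max(DT)`` for in-pupil pixels, DT the Euclidean
    distance to the contour.  Boundary pixels read 1; the deepest interior
    pixel reads 0.  ``center`` is accepted for interface symmetry but the
    field depends on the contour alone.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise DegenerateContour("contour needs at least 3 vertices")
    u, v = contour[:, 0], contour[:, 1]
    # shoelace area; also rejects self-crossing bowties that cancel to ~0
    area = 0.5 * abs(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1)))
    if area < 4.0:
        raise DegenerateContour(f"contour area {area:.2f} px^2 < 4")

    u0, v0 = int(np.floor(u.min())), int(np.floor(v.min()))
    w = int(np.ceil(u.max())) - u0 + 1
    h = int(np.ceil(v.max())) - v0 + 1
    ur, vr = u - u0, v - v0

    boundary = np.zeros((h, w), dtype=bool)
    rr, cc = polygon_perimeter(vr, ur, shape=boundary.shape)
    boundary[rr, cc] = True
    interior = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(vr, ur, shape=interior.shape)
    interior[rr, cc] = True
    interior |= boundary

    dist = distance_transform_edt(~boundary)
    dmax = dist[interior].max()
    if dmax == 0:
        raise DegenerateContour("contour has no interior")
    values = np.full((h, w), np.nan)
    values[interior] = 1.0 - dist[interior] / dmax
    return UncertaintyField(values=values, mask=interior, origin=(u0, v0))
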
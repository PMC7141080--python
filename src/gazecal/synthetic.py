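"""Synthetic eye frames, world frames and calibration sessions with ground truth.

Every downstream stage (pupil detection, marker detection, calibration fit,
IDW correction, evaluation) is testable against these generators.  A session
emulates a head-mounted tracker streaming pupil/marker pairs at 114 Hz: the
marker follows a named trajectory across a 1920x1080 world frame, the true
pupil position is the inverse image of the marker under a known ground-truth
quadratic mapping, and Gaussian pixel noise is added to the pupil centers
only — the marker is the stimulus and is treated as exact.

Because the ground-truth mapping lives in the same full-bivariate-quadratic
family the calibration fits, noiseless sessions admit exact-recovery tests.
An optional ``distortion`` parameter bends the truth out of that family
(a mild projective term) to exercise model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .calibration import design_matrix

WORLD_W, WORLD_H = 1920, 1080
DEFAULT_RATE_HZ = 114.0

TRAJECTORIES = ("head-rotation", "pursuit-rect", "grid9")

__all__ = [
    "EyeImageSpec",
    "GroundTruthSession",
    "default_truth_coeffs",
    "generate_eye_image",
    "generate_session",
    "render_marker",
    "TRAJECTORIES",
    "WORLD_W",
    "WORLD_H",
]


# ---------------------------------------------------------------------------
# eye images


@dataclass
class EyeImageSpec:
    """Parameters of a rendered IR eye frame (dark-pupil regime)."""

    width: int = 640
    height: int = 480
    pupil_center: tuple[float, float] = (320.0, 240.0)  # (u, v) px
    pupil_axes: tuple[float, float] = (40.0, 30.0)  # semi-axes (a, b) px
    pupil_angle: float = 0.0  # degrees
    pupil_gray: int = 20
    iris_gray: int = 120
    sclera_gray: int = 200
    iris_radius: float | None = None  # default 2.2 * max semi-axis
    glint: tuple[tuple[float, float], float] | None = None  # (center, radius)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self):
        if not (self.pupil_gray < self.iris_gray < self.sclera_gray):
            raise ValueError("need pupil_gray < iris_gray < sclera_gray")
        if self.pupil_gray > 60:
            raise ValueError("pupil_gray must be <= 60 (dark pupil regime)")
        a = max(self.pupil_axes)
        u, v = self.pupil_center
        if not (a <= u <= self.width - 1 - a and a <= v <= self.height - 1 - a):
            raise ValueError("pupil ellipse must lie fully inside the frame")


def generate_eye_image(spec: EyeImageSpec):
    """Render the eye frame; returns (uint8 image, truth dict).

    The truth record echoes the pupil center, semi-axes and angle so
    detection accuracy can be scored.  Deterministic under ``spec.seed``.
    """
    spec.validate()
    img = np.full((spec.height, spec.width), spec.sclera_gray, dtype=float)
    u, v = spec.pupil_center
    a, b = spec.pupil_axes
    r_iris = spec.iris_radius or 2.2 * max(a, b)
    rr, cc = draw_disk((v, u), r_iris, shape=img.shape)
    img[rr, cc] = spec.iris_gray
    # skimage's ellipse rotation is counter-clockwise in (row, col)
    rr, cc = draw_ellipse(
        v, u, b, a, shape=img.shape, rotation=np.deg2rad(spec.pupil_angle)
    )
    img[rr, cc] = spec.pupil_gray
    if spec.glint is not None:
        (gu, gv), gr = spec.glint
        rr, cc = draw_disk((gv, gu), gr, shape=img.shape)
        img[rr, cc] = 255
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = {
        "center": tuple(spec.pupil_center),
        "axes": tuple(spec.pupil_axes),
        "angle": spec.pupil_angle,
        "area": np.pi * a * b,
    }
    return img, truth


# ---------------------------------------------------------------------------
# world-frame marker


def render_marker(
    center: tuple[float, float],
    outer_radius: float = 45.0,
    width: int = WORLD_W,
    height: int = WORLD_H,
    cross: bool = True,
    background: int = 230,
) -> np.ndarray:
    """Render the concentric calibration marker on a light frame.

    Ring proportions 3:2:1 (outer black ring / white ring / inner black
    disk), with an optional thin white cross over the center.
    """
    img = np.full((height, width), background, dtype=np.uint8)
    x, y = center
    for radius, gray in (
        (outer_radius, 0),
        (outer_radius * 2 / 3, 255),
        (outer_radius / 3, 0),
    ):
        rr, cc = draw_disk((y, x), radius, shape=img.shape)
        img[rr, cc] = gray
    if cross:
        half = outer_radius / 5.0
        t = max(1, int(round(outer_radius / 30.0)))
        yi, xi = int(round(y)), int(round(x))
        img[
            max(0, yi - t) : yi + t + 1,
            max(0, int(round(x - half))) : int(round(x + half)) + 1,
        ] = 255
        img[
            max(0, int(round(y - half))) : int(round(y + half)) + 1,
            max(0, xi - t) : xi + t + 1,
        ] = 255
    return img


# ---------------------------------------------------------------------------
# ground-truth mapping and trajectories


def default_truth_coeffs() -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth quadratic coefficients over raw pupil basis (1,u,v,uv,u^2,v^2).

    Constructed from a centered form around the eye-frame midpoint (320, 240):
    dominant affine gain mapping the pupil's working range (+-150, +-110 px)
    across the 1920x1080 world frame, plus mild quadratic curvature of a few
    tens of world pixels at the corners.
    """
    u0, v0 = 320.0, 240.0
    # centered coefficients (1, du, dv, du*dv, du^2, dv^2)
    cx = np.array([960.0, 5.8, 0.30, 4.0e-3, 2.0e-3, 1.0e-3])
    cy = np.array([540.0, 0.25, 4.5, -3.0e-3, 1.2e-3, 1.8e-3])

    def expand(c):
        # rewrite sum over (du, dv) powers as coefficients over raw (u, v)
        c0, c1, c2, c3, c4, c5 = c
        out = np.zeros(6)
        out[0] = c0 - c1 * u0 - c2 * v0 + c3 * u0 * v0 + c4 * u0**2 + c5 * v0**2
        out[1] = c1 - c3 * v0 - 2 * c4 * u0
        out[2] = c2 - c3 * u0 - 2 * c5 * v0
        out[3] = c3
        out[4] = c4
        out[5] = c5
        return out

    return expand(cx), expand(cy)


def _truth_forward(uv: np.ndarray, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    A = design_matrix(uv)
    return np.column_stack([A @ cx, A @ cy])


def _truth_inverse(
    xy: np.ndarray, cx: np.ndarray, cy: np.ndarray, tol: float = 1e-12
) -> np.ndarray:
    """Per-point Newton inversion of the quadratic map (world -> pupil).

    The affine part dominates over the working range, so Newton from the
    affine inverse converges to machine precision in a handful of steps.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    J_aff = np.array([[cx[1], cx[2]], [cy[1], cy[2]]])
    J_aff_inv = np.linalg.inv(J_aff)
    b = np.array([cx[0], cy[0]])
    uv = (xy - b) @ J_aff_inv.T
    for _ in range(50):
        f = _truth_forward(uv, cx, cy) - xy
        if np.max(np.abs(f)) < tol:
            break
        u, v = uv[:, 0], uv[:, 1]
        # Jacobian entries of the quadratic surfaces
        dxu = cx[1] + cx[3] * v + 2 * cx[4] * u
        dxv = cx[2] + cx[3] * u + 2 * cx[5] * v
        dyu = cy[1] + cy[3] * v + 2 * cy[4] * u
        dyv = cy[2] + cy[3] * u + 2 * cy[5] * v
        det = dxu * dyv - dxv * dyu
        du = (f[:, 0] * dyv - f[:, 1] * dxv) / det
        dv = (f[:, 1] * dxu - f[:, 0] * dyu) / det
        uv = uv - np.column_stack([du, dv])
    return uv


def _trajectory(name: str, n: int) -> np.ndarray:
    """Noiseless marker path (n, 2) across the world frame."""
    tau = np.arange(n) / max(n - 1, 1)
    cx0, cy0 = WORLD_W / 2.0, WORLD_H / 2.0
    if name == "grid9":
        # 3x3 grid with 15% margin, row-major, equal dwell per point
        xs = np.array([0.15, 0.5, 0.85]) * WORLD_W
        ys = np.array([0.15, 0.5, 0.85]) * WORLD_H
        grid = np.array([(x, y) for y in ys for x in xs])
        idx = np.minimum((tau * 9).astype(int), 8)
        return grid[idx]
    if name == "pursuit-rect":
        # one lap of a centered rectangle perimeter at constant speed
        x0, x1 = 0.15 * WORLD_W, 0.85 * WORLD_W
        y0, y1 = 0.15 * WORLD_H, 0.85 * WORLD_H
        w, h = x1 - x0, y1 - y0
        per = 2 * (w + h)
        s = (tau * per) % per
        pts = np.empty((n, 2))
        for i, si in enumerate(s):
            if si < w:
                pts[i] = (x0 + si, y0)
            elif si < w + h:
                pts[i] = (x1, y0 + si - w)
            elif si < 2 * w + h:
                pts[i] = (x1 - (si - w - h), y1)
            else:
                pts[i] = (x0, y1 - (si - 2 * w - h))
        return pts
    if name == "head-rotation":
        # apparent marker motion under head rotation: spiral that winds
        # inward then back outward over two turns
        r_max = 0.45 * min(WORLD_W, WORLD_H)
        radius = r_max * np.abs(2 * tau - 1)
        theta = 4 * np.pi * tau
        return np.column_stack(
            [cx0 + radius * np.cos(theta), cy0 + radius * np.sin(theta)]
        )
    raise ValueError(f"unknown trajectory {name!r}; choose from {TRAJECTORIES}")


@dataclass
class GroundTruthSession:
    """A generated session: observed pupil/marker table plus noiseless truth."""

    trajectory: str
    rate_hz: float
    duration_s: float
    noise_sd_px: float
    seed: int
    coeff_x: np.ndarray
    coeff_y: np.ndarray
    table: pd.DataFrame = field(repr=False)  # observed stream
    truth: pd.DataFrame = field(repr=False)  # noiseless pupil + marker


def generate_session(
    trajectory: str = "head-rotation",
    duration_s: float = 5.0,
    rate_hz: float = DEFAULT_RATE_HZ,
    noise_sd_px: float = 1.0,
    seed: int = 0,
    truth_coeffs: tuple[np.ndarray, np.ndarray] | None = None,
    distortion: float = 0.0,
    drift_ratio: float = 2.0,
    drift_tau_s: float = 0.5,
) -> GroundTruthSession:
    """Generate a timestamped pupil/marker pair stream with known truth.

    ``floor(rate_hz * duration_s)`` rows at 1000/rate_hz ms steps; marker
    positions follow the named trajectory exactly, pupil centers are the
    inverse image of the markers under the ground-truth quadratic plus
    measurement noise scaled by ``noise_sd_px``.

    The noise has two components, both zero when ``noise_sd_px`` is 0:
    frame-to-frame Gaussian jitter of sd ``noise_sd_px`` (pupil-detection
    precision), and a slow drift — a Gaussian process with correlation time
    ``drift_tau_s`` seconds and RMS ``drift_ratio * noise_sd_px`` —
    emulating the temporally correlated gaze error of real recordings
    (headset slippage, pursuit lag, residual head-movement parallax).  The
    drift is what residual-based correction can recover; set
    ``drift_ratio=0`` for pure white noise.

    ``distortion`` adds a projective bend to the true pupil positions,
    taking the truth outside the fitted quadratic family.
    """
    if not 0 < duration_s <= 12:
        raise ValueError("duration_s must be in (0, 12] seconds")
    cx, cy = truth_coeffs if truth_coeffs is not None else default_truth_coeffs()
    n = int(np.floor(rate_hz * duration_s))
    t_ms = np.rint(np.arange(n) * 1000.0 / rate_hz).astype(int)
    marker = _trajectory(trajectory, n)
    pupil_true = _truth_inverse(marker, cx, cy)
    if distortion != 0.0:
        du = pupil_true[:, 0] - 320.0
        dv = pupil_true[:, 1] - 240.0
        denom = 1.0 + distortion * (du + dv) / 640.0
        pupil_true = np.column_stack([320.0 + du / denom, 240.0 + dv / denom])
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd_px, pupil_true.shape)
    if noise_sd_px > 0 and drift_ratio > 0 and n > 2:
        white = rng.normal(0.0, 1.0, pupil_true.shape)
        smooth = gaussian_filter1d(white, sigma=drift_tau_s * rate_hz, axis=0)
        sd = smooth.std(axis=0)
        sd[sd == 0] = 1.0
        noise = noise + smooth / sd * (drift_ratio * noise_sd_px)
    pupil_obs = pupil_true + noise
    table = pd.DataFrame(
        {
            "timestamp": t_ms,
            "pupil_u": pupil_obs[:, 0],
            "pupil_v": pupil_obs[:, 1],
            "marker_x": marker[:, 0],
            "marker_y": marker[:, 1],
        }
    )
    truth = pd.DataFrame(
        {
            "timestamp": t_ms,
            "pupil_u": pupil_true[:, 0],
            "pupil_v": pupil_true[:, 1],
            "marker_x": marker[:, 0],
            "marker_y": marker[:, 1],
        }
    )
    return GroundTruthSession(
        trajectory=trajectory,
        rate_hz=rate_hz,
        duration_s=duration_s,
        noise_sd_px=noise_sd_px,
        seed=seed,
        coeff_x=cx,
        coeff_y=cy,
        table=table,
        truth=truth,
    )
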
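"""Pupil-to-world gaze mapping: pairing, splitting, quadratic fit, residuals.

The mapping is a pair of bivariate second-order polynomial surfaces

    x = a0 + a1*u + a2*v + a3*u*v + a4*u^2 + a5*v^2
    y = b0 + b1*u + b2*v + b3*u*v + b4*u^2 + b5*v^2

fitted by SVD least squares to calibration pairs (pupil center in eye-camera
pixels, marker center in world-camera pixels).  Pupil coordinates are
standardized (zero mean, unit scale per axis) before fitting, purely to
condition the design matrix; the stored normalization makes predictions
independent of the choice on well-conditioned data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateGeometry, InsufficientCalibrationPoints

BASIS_NAMES = ("1", "u", "v", "u*v", "u^2", "v^2")

__all__ = [
    "CalibrationPair",
    "MappingModel",
    "ResidualSet",
    "pair_streams",
    "split_pairs",
    "design_matrix",
    "fit_mapping",
    "predict",
    "reprojection_residuals",
    "BASIS_NAMES",
]


@dataclass(frozen=True)
class CalibrationPair:
    """One simultaneous (pupil center, marker center) observation."""

    timestamp: int  # ms from session start
    pupil: tuple[float, float]  # (u, v) eye-camera px
    marker: tuple[float, float]  # (x, y) world-camera px


@dataclass
class MappingModel:
    """Two 6-coefficient quadratic surfaces plus the pupil standardization.

    ``coeff_x`` / ``coeff_y`` are over the basis (1, u, v, u*v, u^2, v^2) in
    *standardized* pupil coordinates ``(u - mean) / scale``.
    """

    coeff_x: np.ndarray
    coeff_y: np.ndarray
    norm_mean: np.ndarray  # (2,) per pupil axis
    norm_scale: np.ndarray  # (2,) per pupil axis
    train_pupil_bbox: np.ndarray  # (2, 2) [[umin, vmin], [umax, vmax]]

    def __post_init__(self):
        self.coeff_x = np.asarray(self.coeff_x, dtype=float)
        self.coeff_y = np.asarray(self.coeff_y, dtype=float)
        if self.coeff_x.shape != (6,) or self.coeff_y.shape != (6,):
            raise ValueError("each coefficient vector must have 6 entries")
        if not (np.isfinite(self.coeff_x).all() and np.isfinite(self.coeff_y).all()):
            raise ValueError("non-finite mapping coefficients")


@dataclass
class ResidualSet:
    """Correction vectors v_i = marker - reprojection at the calibration pairs.

    Node positions are the actual marker centers; these are the nodes the
    inverse-distance correction interpolates between.
    """

    node_xy: np.ndarray  # (N, 2) marker centers, world px
    node_t: np.ndarray  # (N,) timestamps ms
    vectors: np.ndarray  # (N, 2) correction vectors, world px
    reprojections: np.ndarray = field(default=None)  # (N, 2) model estimates

    def __len__(self) -> int:
        return len(self.node_xy)


def pair_streams(pupils, markers, max_dt_ms: float = 9.0):
    """Match each pupil sample to the nearest-timestamp marker sample.

    Both inputs are sequences of objects with ``timestamp`` (ms) and a
    ``center`` attribute, or (timestamp, x, y) tuples.  Samples farther than
    ``max_dt_ms`` from any counterpart are dropped.  Equidistant markers
    break toward the later sample.

    Returns ``(pairs, n_dropped)`` where pairs is a list of CalibrationPair.
    """

    def unpack(s):
        if hasattr(s, "timestamp"):
            return float(s.timestamp), tuple(map(float, s.center))
        t, x, y = s[0], s[1], s[2]
        return float(t), (float(x), float(y))

    if len(pupils) == 0 or len(markers) == 0:
        import warnings

        warnings.warn("empty pupil or marker stream; no pairs formed")
        return [], len(pupils) + len(markers)

    pt = np.array([unpack(p)[0] for p in pupils])
    mt = np.array([unpack(m)[0] for m in markers])
    pairs = []
    dropped = 0
    for i, p in enumerate(pupils):
        t, (u, v) = unpack(p)
        j = int(np.searchsorted(mt, t))
        # candidates: previous and next marker; tie breaks to the later one
        best = None
        for k in (j, j - 1):  # j (later/equal) checked first wins ties
            if 0 <= k < len(mt):
                dt = abs(mt[k] - t)
                if dt <= max_dt_ms and (best is None or dt < best[0]):
                    best = (dt, k)
        if best is None:
            dropped += 1
            continue
        _, (mx, my) = unpack(markers[best[1]])
        pairs.append(CalibrationPair(int(round(t)), (u, v), (mx, my)))
    return pairs, dropped


def split_pairs(pairs, split_fraction: float = 0.5, seed: int = 0):
    """Uniform random split into (calibration X, evaluation Y), seeded.

    The calibration side gets ``round(n * split_fraction)`` pairs and must
    hold at least 6 (the quadratic fit's minimum); the evaluation side must
    be non-empty.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    n = len(pairs)
    n_cal = int(round(n * split_fraction))
    if n_cal < 6:
        raise InsufficientCalibrationPoints(
            f"split of {n} pairs at fraction {split_fraction} leaves "
            f"{n_cal} calibration pairs; at least 6 required"
        )
    if n - n_cal < 1:
        raise InsufficientCalibrationPoints("evaluation set would be empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    take = np.sort(order[:n_cal])
    rest = np.sort(order[n_cal:])
    pairs = list(pairs)
    return [pairs[i] for i in take], [pairs[i] for i in rest]


def design_matrix(uv: np.ndarray) -> np.ndarray:
    """Quadratic design matrix with columns (1, u, v, u*v, u^2, v^2)."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    u, v = uv[:, 0], uv[:, 1]
    return np.column_stack([np.ones_like(u), u, v, u * v, u * u, v * v])


def _pairs_arrays(pairs):
    pupil = np.array([p.pupil for p in pairs], dtype=float)
    marker = np.array([p.marker for p in pairs], dtype=float)
    t = np.array([p.timestamp for p in pairs], dtype=float)
    return pupil, marker, t


def fit_mapping(pairs, standardize: bool = True) -> MappingModel:
    """Fit both quadratic surfaces by SVD least squares.

    Raises DegenerateGeometry (naming the deficient basis direction) when the
    pupil geometry does not span all six basis functions, e.g. all pupil
    points on a straight line.
    """
    if len(pairs) < 6:
        raise InsufficientCalibrationPoints(
            f"{len(pairs)} pairs; the quadratic fit needs at least 6"
        )
    pupil, marker, _ = _pairs_arrays(pairs)
    if standardize:
        mean = pupil.mean(axis=0)
        scale = pupil.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(2)
        scale = np.ones(2)
    z = (pupil - mean) / scale
    A = design_matrix(z)

    # rank check via SVD; the right singular vector of the vanishing singular
    # value names which basis direction the geometry fails to excite
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    tol = s[0] * max(A.shape) * np.finfo(float).eps * 1e3
    if s[-1] <= tol:
        null = Vt[-1]
        name = BASIS_NAMES[int(np.argmax(np.abs(null)))]
        raise DegenerateGeometry(
            "calibration pupil geometry is rank-deficient "
            f"(singular value {s[-1]:.3e}); deficient basis direction: {name}",
            deficient_basis=name,
        )
    # SVD pseudo-inverse solve for both target coordinates at once
    coeffs = Vt.T @ ((U.T @ marker) / s[:, None])
    bbox = np.vstack([pupil.min(axis=0), pupil.max(axis=0)])
    return MappingModel(coeffs[:, 0], coeffs[:, 1], mean, scale, bbox)


def predict(model: MappingModel, pupil, return_flags: bool = False):
    """Evaluate the fitted surfaces at pupil point(s).

    Extrapolation is permitted; with ``return_flags=True`` the second return
    value marks points outside the calibration pupil bounding box, where the
    quadratic is unreliable.
    """
    p = np.asarray(pupil, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    z = (p - model.norm_mean) / model.norm_scale
    A = design_matrix(z)
    out = np.column_stack([A @ model.coeff_x, A @ model.coeff_y])
    if return_flags:
        lo, hi = model.train_pupil_bbox
        flags = np.any((p < lo) | (p > hi), axis=1)
        if single:
            return out[0], bool(flags[0])
        return out, flags
    return out[0] if single else out


def reprojection_residuals(model: MappingModel, pairs) -> ResidualSet:
    """Correction vectors v_i = marker_i - predict(pupil_i) at each pair."""
    pupil, marker, t = _pairs_arrays(pairs)
    repro = predict(model, pupil)
    return ResidualSet(
        node_xy=marker.copy(),
        node_t=t.copy(),
        vectors=marker - repro,
        reprojections=repro,
    )
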
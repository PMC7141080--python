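"""Qualitative gaze-uncertainty visualizations over the world frame.

Two kernel families accumulate recorded samples into a density map:

* gaussian — a unit-mass isotropic Gaussian per gaze point, the classical
  fixation heat map; every sample spreads identically.
* pupil-polygon — the pupil contour projected through the gaze mapping into
  world coordinates, filled with its interior distance-transform kernel
  (1 at the deepest point, 0 at the edge) and left unnormalized, so larger
  or more elongated pupils — more uncertain center estimates — spread more
  mass over a larger support.

A bump-mapped (Lambertian-shaded) rendering emphasizes gradients of the
accumulated height field, and an IDW-interpolated error map extends the
calibration residual norms to every world location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

from .calibration import MappingModel, predict
from .correction import CorrectionField, idw_vector

WORLD_W, WORLD_H = 1920, 1080
DEFAULT_FACTOR = 4
DEFAULT_SIGMA_PX = 20.0

__all__ = [
    "UncertaintyMap",
    "project_contour",
    "accumulate",
    "bump_render",
    "error_map",
]


@dataclass
class UncertaintyMap:
    """Accumulated uncertainty density over a downsampled world raster."""

    kernel_kind: str = "gaussian"  # or "pupil-polygon"
    factor: int = DEFAULT_FACTOR  # integer downsampling of the world raster
    grid: np.ndarray = field(default=None, repr=False)
    n_samples: int = 0
    n_skipped: int = 0

    def __post_init__(self):
        if self.grid is None:
            self.grid = np.zeros(
                (WORLD_H // self.factor, WORLD_W // self.factor), dtype=float
            )


def project_contour(model: MappingModel, contour: np.ndarray):
    """Map a pupil contour into world coordinates vertex by vertex.

    Returns ``(world_polygon, folded)``.  ``folded`` is True when the mapped
    polygon self-intersects — the signature of the quadratic folding over
    when extrapolating far outside the calibration region.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.shape[0] < 5:
        raise ValueError("contour needs at least 5 vertices")
    world = predict(model, contour)
    folded = not Polygon(world).is_valid
    return world, folded


def _add_gaussian(grid: np.ndarray, x: float, y: float, sigma_cells: float):
    """Add one unit-mass Gaussian centred at raster coords (x, y)."""
    h, w = grid.shape
    half = int(np.ceil(4 * sigma_cells))
    c0, c1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    r0, r1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    c0, c1 = max(c0, 0), min(c1, w)
    r0, r1 = max(r0, 0), min(r1, h)
    if c0 >= c1 or r0 >= r1:
        return
    xs = np.arange(c0, c1) - x
    ys = np.arange(r0, r1) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma_cells**2))
    grid[r0:r1, c0:c1] += g / g.sum()


def _polygon_kernel(poly_cells: np.ndarray, shape):
    """Interior distance-transform kernel: 1 at the deepest point, 0 at edge."""
    x, y = poly_cells[:, 0], poly_cells[:, 1]
    boundary = np.zeros(shape, dtype=bool)
    rr, cc = polygon_perimeter(y, x, shape=shape)
    boundary[rr, cc] = True
    interior = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(y, x, shape=shape)
    interior[rr, cc] = True
    interior |= boundary
    if not interior.any() or not boundary.any():
        return None
    dist = distance_transform_edt(~boundary)
    dmax = dist[interior].max()
    if dmax == 0:
        return None
    kernel = np.zeros(shape, dtype=float)
    kernel[interior] = dist[interior] / dmax
    return kernel


def accumulate(
    umap: UncertaintyMap, samples, sigma_px: float = DEFAULT_SIGMA_PX
) -> UncertaintyMap:
    """Accumulate gaze samples into the map, in place; returns the map.

    gaussian maps take (x, y) gaze points in world pixels; pupil-polygon
    maps take (K, 2) projected contour polygons in world pixels.  Degenerate
    polygons are skipped and counted in ``n_skipped``.
    """
    f = umap.factor
    for s in samples:
        arr = np.asarray(s, dtype=float)
        if umap.kernel_kind == "gaussian":
            x, y = arr.ravel()[:2]
            _add_gaussian(umap.grid, x / f, y / f, sigma_px / f)
            umap.n_samples += 1
        elif umap.kernel_kind == "pupil-polygon":
            kernel = _polygon_kernel(arr / f, umap.grid.shape)
            if kernel is None:
                umap.n_skipped += 1
                continue
            umap.grid += kernel
            umap.n_samples += 1
        else:
            raise ValueError(f"unknown kernel kind {umap.kernel_kind!r}")
    return umap


def bump_render(
    grid: np.ndarray, light_azimuth_deg: float = 315.0, light_elevation_deg: float = 45.0
) -> np.ndarray:
    """Lambertian shading of the map height field under a directional light.

    Central-difference gradients define the surface normals; output is
    min-max scaled to [0, 1].  A constant field shades to uniform 0.5.
    """
    grid = np.asarray(grid, dtype=float)
    gy, gx = np.gradient(grid)
    az = np.deg2rad(light_azimuth_deg)
    el = np.deg2rad(light_elevation_deg)
    light = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    shade = (-gx * light[0] - gy * light[1] + light[2]) / norm
    shade = np.clip(shade, 0.0, None)
    lo, hi = shade.min(), shade.max()
    if hi - lo < 1e-12:
        return np.full_like(grid, 0.5)
    return (shade - lo) / (hi - lo)


def error_map(
    field_: CorrectionField,
    width: int = WORLD_W,
    height: int = WORLD_H,
    factor: int = DEFAULT_FACTOR,
) -> np.ndarray:
    """IDW-interpolated residual-norm map over the world raster.

    Every raster cell holds |idw_vector| at the cell center using all
    calibration nodes; cells coinciding with a node hold that node's |v_i|.
    """
    w, h = width // factor, height // factor
    xs = (np.arange(w) + 0.5) * factor
    ys = (np.arange(h) + 0.5) * factor
    nodes = field_.nodes
    vec = nodes.vectors
    xy = nodes.node_xy
    out = np.empty((h, w), dtype=float)
    for j, y in enumerate(ys):  # row-chunked to bound memory
        d = np.hypot(xy[:, 0][None, :] - xs[:, None], xy[:, 1][None, :] - y)
        hit_rows = np.flatnonzero((d == 0.0).any(axis=1))
        d[d == 0.0] = np.inf  # placeholder; those cells redone below
        wgt = d ** -field_.r
        with np.errstate(invalid="ignore"):
            row_v = (wgt @ vec) / wgt.sum(axis=1, keepdims=True)
        for i in hit_rows:
            row_v[i] = idw_vector(field_, (xs[i], y))
        out[j] = np.hypot(row_v[:, 0], row_v[:, 1])
    return out
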
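"""Session CSV I/O, data cleansing, map export, and pipeline configuration.

A session is stored as a comma-separated file (UTF-8, dot decimals, one
header row) with the five columns

    timestamp,pupil_u,pupil_v,marker_x,marker_y

timestamps in integer milliseconds from session start, pupil coordinates in
eye-camera pixels, marker coordinates in world-camera pixels.  Cleansing
drops duplicated points — rows identical in all four coordinates at the
stored precision of 6 decimals — keeping the first occurrence; the duplicate
pupil entry and its paired marker entry go together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .exceptions import FormatError, ParseError

logger = logging.getLogger("gazecal")

SESSION_COLUMNS = ("timestamp", "pupil_u", "pupil_v", "marker_x", "marker_y")
COORD_COLUMNS = SESSION_COLUMNS[1:]
STORED_DECIMALS = 6

__all__ = [
    "PipelineConfig",
    "read_session",
    "write_session",
    "cleanse",
    "classify_session",
    "session_duration_s",
    "write_map",
    "read_map_text",
    "SESSION_COLUMNS",
]


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    r            IDW power (dimensionless), default 2
    window_ms    time window T of the windowed IDW, milliseconds
    distance_cm  eye-to-plane viewing distance for angular errors
    px_per_cm    world-camera pixels per centimetre on the stimulus plane
    split_fraction  share of pairs used for calibration (rest evaluate)
    """

    r: float = 2.0
    window_ms: float = 200.0
    distance_cm: float = 75.0
    px_per_cm: float = 37.0
    split_fraction: float = 0.5
    seed: int = 0
    short_long_threshold_s: float = 6.0
    max_calibration_s: float = 12.0

    def __post_init__(self):
        for name in (
            "r",
            "window_ms",
            "distance_cm",
            "px_per_cm",
            "short_long_threshold_s",
            "max_calibration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat ``key: value`` text file (YAML-compatible)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_file(self, path) -> None:
        Path(path).write_text(
            "".join(f"{k}: {v}\n" for k, v in asdict(self).items())
        )


def cleanse(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove duplicated points' entries and their corresponding pairs.

    Rows identical in all four coordinates at 6-decimal precision are
    duplicates; the first occurrence is kept.  Returns (table, n_removed).
    Idempotent.
    """
    rounded = table[list(COORD_COLUMNS)].round(STORED_DECIMALS)
    keep = ~rounded.duplicated(keep="first")
    removed = int((~keep).sum())
    out = table.loc[keep].sort_values("timestamp", kind="stable")
    return out.reset_index(drop=True), removed


def read_session(path) -> pd.DataFrame:
    """Read and cleanse a session CSV; logs the number of removed rows."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    missing = [c for c in SESSION_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(raw) == 0:
        logger.warning("%s: session file has a header but no rows", path)
        return pd.DataFrame({c: pd.Series(dtype=float) for c in SESSION_COLUMNS})
    table = pd.DataFrame()
    for col in SESSION_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at data row {row + 1}",
                row=row + 1,
            )
        table[col] = vals
    if not np.isfinite(table[list(COORD_COLUMNS)].to_numpy()).all():
        raise ParseError(f"{path}: non-finite coordinate value")
    table["timestamp"] = table["timestamp"].astype(np.int64)
    table, removed = cleanse(table)
    if removed:
        logger.info("%s: removed %d duplicated row(s)", path, removed)
    return table


def write_session(table: pd.DataFrame, path) -> None:
    """Write a session table in the canonical CSV layout."""
    out = table[list(SESSION_COLUMNS)].copy()
    out[list(COORD_COLUMNS)] = out[list(COORD_COLUMNS)].round(STORED_DECIMALS)
    out.to_csv(path, index=False)


def session_duration_s(table: pd.DataFrame) -> float:
    if len(table) < 2:
        return 0.0
    ts = table["timestamp"]
    return float(ts.iloc[-1] - ts.iloc[0]) / 1000.0


def classify_session(duration_s: float, threshold_s: float = 6.0, max_s: float = 12.0) -> str:
    """Label a calibration by its duration: short (<6 s), long (6-12 s), excluded (>12 s)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if duration_s < threshold_s:
        return "short"
    if duration_s <= max_s:
        return "long"
    return "excluded"


def write_map(grid: np.ndarray, path) -> None:
    """Export a map grid as an 8-bit grayscale PNG plus a text float matrix.

    The PNG is min-max normalized; the sibling ``.txt`` stores the raw grid
    row-major, space-separated, 6 decimals, so it round-trips numerically.
    """
    grid = np.asarray(grid, dtype=float)
    if not np.isfinite(grid).all() or (grid < 0).any():
        raise ValueError("map grid must be finite and non-negative")
    path = Path(path)
    lo, hi = grid.min(), grid.max()
    scaled = np.zeros_like(grid) if hi == lo else (grid - lo) / (hi - lo)
    img = (np.rint(scaled * 255)).astype(np.uint8)
    try:
        Image.fromarray(img, mode="L").save(path.with_suffix(".png"))
        np.savetxt(path.with_suffix(".txt"), grid, fmt="%.6f")
    except OSError as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc


def read_map_text(path) -> np.ndarray:
    """Read back the text matrix written by :func:`write_map`."""
    return np.atleast_2d(np.loadtxt(Path(path).with_suffix(".txt")))
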
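"""Quantitative evaluation: error norms, unit conversions, reductions, reports.

The Mean Angular Error (MAE) of a calibration is the mean of the Euclidean
error norms between estimated and actual gaze locations on the evaluation
set, reported in centimetres on the stimulus plane and in degrees of visual
angle.  A pixel error converts to centimetres through the plane scale
(px_per_cm) and to degrees through theta = arctan(e_cm / D) with D the
viewing distance (75 cm in the reference setup); each per-point error is
converted before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationPair,
    fit_mapping,
    predict,
    reprojection_residuals,
    split_pairs,
)
from .correction import CorrectionField, correct_many
from .io_sessions import PipelineConfig

METHODS = ("raw", "idw", "midw")

__all__ = [
    "EvaluationResult",
    "error_norms",
    "px_to_cm",
    "cm_to_deg",
    "reduction_percent",
    "pairs_from_table",
    "evaluate_session",
    "results_table",
    "METHODS",
]


@dataclass
class EvaluationResult:
    """Per-method evaluation summary for one session."""

    method: str  # raw | idw | midw
    session_label: str  # short | long | excluded
    n_eval: int
    errors_px: np.ndarray
    mae_px: float
    mae_cm: float
    sd_cm: float
    mae_deg: float
    sd_deg: float


def error_norms(estimates, truths) -> np.ndarray:
    """Euclidean error norm per (estimate, truth) pair, in input units."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    tru = np.atleast_2d(np.asarray(truths, dtype=float))
    if est.shape != tru.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {tru.shape}")
    return np.hypot(*(est - tru).T)


def px_to_cm(e_px, px_per_cm: float):
    """Pixel error on the stimulus plane to centimetres."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    return np.asarray(e_px, dtype=float) / px_per_cm


def cm_to_deg(e_cm, distance_cm: float = 75.0):
    """Centimetre error on the plane to degrees of visual angle.

    theta = arctan(e_cm / distance_cm), the angle the error subtends at the
    eye for a plane at the given viewing distance.
    """
    if distance_cm <= 0:
        raise ValueError("distance_cm must be positive")
    return np.degrees(np.arctan(np.asarray(e_cm, dtype=float) / distance_cm))


def reduction_percent(mae_ref: float, mae_new: float) -> float:
    """Percent error reduction of ``mae_new`` relative to ``mae_ref``."""
    if mae_ref <= 0:
        raise ValueError("reference MAE must be positive")
    return 100.0 * (mae_ref - mae_new) / mae_ref


def pairs_from_table(table: pd.DataFrame) -> list[CalibrationPair]:
    """Convert a session table's rows into CalibrationPair objects."""
    return [
        CalibrationPair(
            int(row.timestamp),
            (float(row.pupil_u), float(row.pupil_v)),
            (float(row.marker_x), float(row.marker_y)),
        )
        for row in table.itertuples()
    ]


def evaluate_session(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict[str, EvaluationResult]:
    """Split, fit, and score raw / IDW / windowed-IDW on the evaluation set.

    Deterministic given ``config.seed``.  The recorded marker positions act
    as the actual gaze locations (the participant fixates the marker).
    """
    from .io_sessions import classify_session, session_duration_s

    config = config or PipelineConfig()
    pairs = pairs_from_table(table)
    cal, ev = split_pairs(pairs, config.split_fraction, config.seed)
    model = fit_mapping(cal)
    field = CorrectionField(
        reprojection_residuals(model, cal), r=config.r, window_ms=config.window_ms
    )
    label = classify_session(
        max(session_duration_s(table), 1e-9),
        config.short_long_threshold_s,
        config.max_calibration_s,
    )
    pupil_ev = np.array([p.pupil for p in ev])
    marker_ev = np.array([p.marker for p in ev])
    raw = predict(model, pupil_ev)
    estimates = {
        "raw": raw,
        "idw": correct_many(field, raw, "idw"),
        "midw": correct_many(field, raw, "midw"),
    }
    out = {}
    for method, est in estimates.items():
        e_px = error_norms(est, marker_ev)
        e_cm = px_to_cm(e_px, config.px_per_cm)
        e_deg = cm_to_deg(e_cm, config.distance_cm)
        out[method] = EvaluationResult(
            method=method,
            session_label=label,
            n_eval=len(ev),
            errors_px=e_px,
            mae_px=float(e_px.mean()),
            mae_cm=float(e_cm.mean()),
            sd_cm=float(e_cm.std(ddof=1)) if len(e_cm) > 1 else 0.0,
            mae_deg=float(e_deg.mean()),
            sd_deg=float(e_deg.std(ddof=1)) if len(e_deg) > 1 else 0.0,
        )
    return out


def results_table(results: dict[str, EvaluationResult]) -> pd.DataFrame:
    """Report rows (method, MAE_cm, SD_cm, MAE_deg, SD_deg, n_eval, reduction)."""
    raw_mae = results["raw"].mae_cm
    rows = []
    for method in METHODS:
        r = results[method]
        rows.append(
            {
                "method": method,
                "MAE_cm": r.mae_cm,
                "SD_cm": r.sd_cm,
                "MAE_deg": r.mae_deg,
                "SD_deg": r.sd_deg,
                "n_eval": r.n_eval,
                "reduction_vs_raw_percent": (
                    reduction_percent(raw_mae, r.mae_cm) if raw_mae > 0 else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
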
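"""Model/Results front end for the gaze-mapping pipeline.

`GazeMapping` is built from paired pupil/marker data (a DataFrame, a CSV
file, or a list of CalibrationPair); its :meth:`fit` returns a
`GazeMappingResults` carrying the fitted quadratic coefficients, the
calibration residual set, and methods to predict, correct (IDW / windowed
IDW), evaluate, and summarize.

Example
-------
>>> from gazecal import GazeMapping, synthetic
>>> sess = synthetic.generate_session("pursuit-rect", duration_s=4, seed=1)
>>> res = GazeMapping.from_dataframe(sess.table, seed=1).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal
from .correction import CorrectionField, correct_many
from .io_sessions import PipelineConfig, read_session
from .metrics import EvaluationResult, evaluate_session, results_table

__all__ = ["GazeMapping", "GazeMappingResults"]


class GazeMapping:
    """Quadratic pupil-to-world gaze mapping model over paired samples.

    Parameters
    ----------
    pairs : list of CalibrationPair
        The full session; split into calibration/evaluation sides at fit
        time according to ``config.split_fraction`` and ``config.seed``.
    config : PipelineConfig, optional
        Pipeline parameters (IDW power, time window, split, units).
    """

    def __init__(self, pairs, config: PipelineConfig | None = None):
        self.pairs = list(pairs)
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, config=None, **config_kw):
        from .metrics import pairs_from_table

        if config is None and config_kw:
            config = PipelineConfig(**config_kw)
        return cls(pairs_from_table(table), config)

    @classmethod
    def from_csv(cls, path, config=None, **config_kw):
        return cls.from_dataframe(read_session(path), config, **config_kw)

    def fit(self, split: bool = True) -> "GazeMappingResults":
        """Split (optional), fit by SVD least squares, compute residuals."""
        if split:
            cal_pairs, eval_pairs = cal.split_pairs(
                self.pairs, self.config.split_fraction, self.config.seed
            )
        else:
            cal_pairs, eval_pairs = self.pairs, []
        model = cal.fit_mapping(cal_pairs)
        residuals = cal.reprojection_residuals(model, cal_pairs)
        return GazeMappingResults(self, model, residuals, cal_pairs, eval_pairs)


class GazeMappingResults:
    """Fitted gaze mapping with residual-based correction and evaluation."""

    def __init__(self, parent, mapping, residuals, cal_pairs, eval_pairs):
        self.model = parent
        self.mapping: cal.MappingModel = mapping
        self.residuals: cal.ResidualSet = residuals
        self.cal_pairs = cal_pairs
        self.eval_pairs = eval_pairs
        cfg = parent.config
        self.field = CorrectionField(residuals, r=cfg.r, window_ms=cfg.window_ms)

    @property
    def params(self) -> pd.DataFrame:
        """Fitted coefficients over the standardized quadratic basis."""
        return pd.DataFrame(
            {"coeff_x": self.mapping.coeff_x, "coeff_y": self.mapping.coeff_y},
            index=list(cal.BASIS_NAMES),
        )

    def predict(self, pupil, method: str = "raw", return_flags: bool = False):
        """Estimated gaze for pupil point(s), optionally IDW-corrected."""
        if return_flags:
            est, flags = cal.predict(self.mapping, pupil, return_flags=True)
        else:
            est = cal.predict(self.mapping, pupil)
        if method != "raw":
            single = np.asarray(pupil, dtype=float).ndim == 1
            est = correct_many(self.field, est, method)
            if single:
                est = est[0]
        return (est, flags) if return_flags else est

    def correct(self, points, method: str = "midw") -> np.ndarray:
        """Correct already-estimated world points with IDW / windowed IDW."""
        return correct_many(self.field, points, method)

    def evaluate(self) -> dict[str, EvaluationResult]:
        """Score raw / IDW / windowed IDW on the held-out evaluation side."""
        if not self.eval_pairs:
            raise ValueError("model was fitted without an evaluation split")
        table = pd.DataFrame(
            {
                "timestamp": [p.timestamp for p in self.model.pairs],
                "pupil_u": [p.pupil[0] for p in self.model.pairs],
                "pupil_v": [p.pupil[1] for p in self.model.pairs],
                "marker_x": [p.marker[0] for p in self.model.pairs],
                "marker_y": [p.marker[1] for p in self.model.pairs],
            }
        )
        return evaluate_session(table, self.model.config)

    def summary(self) -> str:
        """Plain-text report: coefficients, residual scale, evaluation MAEs."""
        cfg = self.model.config
        lines = [
            "Gaze mapping (bivariate quadratic, SVD least squares)",
            "=" * 56,
            f"calibration pairs: {len(self.cal_pairs)}   "
            f"evaluation pairs: {len(self.eval_pairs)}",
            f"IDW power r = {cfg.r:g}   window T = {cfg.window_ms:g} ms",
            "",
            self.params.to_string(float_format=lambda x: f"{x:12.5f}"),
            "",
            f"mean |residual| at calibration nodes: "
            f"{np.hypot(*self.residuals.vectors.T).mean():.4f} px",
        ]
        if self.eval_pairs:
            tab = results_table(self.evaluate())
            lines += ["", tab.to_string(index=False, float_format=lambda x: f"{x:.4f}")]
        return "\n".join(lines)
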
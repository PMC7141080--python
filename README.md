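# gazecal

Calibration and uncertainty analysis for monocular head-mounted eye trackers.

A head-mounted tracker pairs an IR eye camera (the pupil) with a forward-facing
world camera (the scene). Estimating where the wearer looks means mapping the
detected pupil center $(u, v)$, in eye-camera pixels, to a gaze point $(x, y)$
in world-camera pixels. `gazecal` implements that pipeline end to end:

1. **Dark-pupil detection** — histogram-threshold + morphology + sub-pixel
   contour + algebraic ellipse fit, with a distance-transform *uncertainty
   field* over the pupil area (1 on the contour, 0 at the deepest interior
   point) expressing where the true center could be.
2. **Marker detection** — the concentric black/white/black calibration marker
   is localized by its nested-contour signature; the innermost disk centroid
   is the measured center.
3. **Calibration** — paired pupil/marker samples, collected while the wearer
   fixates a marker during head rotation, smooth pursuit, or a 9-point grid,
   are fitted by SVD least squares with a bivariate quadratic per output axis:

   $$x = a_0 + a_1 u + a_2 v + a_3 uv + a_4 u^2 + a_5 v^2$$

4. **Correction** — the fit's residuals at the calibration points, the vectors
   $v_i = \text{marker}_i - \text{reprojection}_i$, are interpolated to any
   gaze estimate $p$ by inverse-distance weighting (Shepard interpolation),

   $$v_p = \frac{\sum_i v_i\, d_i^{-r}}{\sum_i d_i^{-r}}, \qquad r = 2,$$

   either over **all** nodes (IDW) or — the *time-windowed* variant (MIDW) —
   only over nodes recorded within $\pm T$ ms ($T = 200$) of the timestamp of
   the node spatially nearest to $p$, which keeps the correction local to one
   stretch of the calibration sweep and recovers temporally correlated error.
5. **Evaluation & maps** — Mean Angular Error (mean Euclidean error norm) in
   cm on the stimulus plane and in degrees of visual angle
   ($\theta = \arctan(e/D)$, $D = 75$ cm), plus uncertainty heat maps
   (isotropic Gaussian kernels, or projected pupil-polygon kernels whose
   shape follows each pupil), bump-mapped renderings, and an IDW-interpolated
   error map over the whole field of view.

A synthetic-session generator with a known ground-truth mapping makes every
stage testable without recordings.

## Worked example

```python
from gazecal import GazeMapping, PipelineConfig, synthetic

sess = synthetic.generate_session("head-rotation", duration_s=5.0,
                                  noise_sd_px=1.0, seed=42)
res = GazeMapping.from_dataframe(sess.table, PipelineConfig(seed=42)).fit()
print(res.summary())
```

```
Gaze mapping (bivariate quadratic, SVD least squares)
========================================================
calibration pairs: 285   evaluation pairs: 285
IDW power r = 2   window T = 200 ms

         coeff_x      coeff_y
1      958.17268    540.85725
u      205.17530     12.75865
v       15.44949    196.02269
u*v      4.16688     -3.84027
u^2     -4.07049      1.51099
v^2     -4.73991      1.13496

mean |residual| at calibration nodes: 9.3089 px

method  MAE_cm  SD_cm  MAE_deg  SD_deg  n_eval  reduction_vs_raw_percent
   raw  0.2520 0.1364   0.1925  0.1042     285                    0.0000
   idw  0.2081 0.1178   0.1590  0.0900     285                   17.4165
  midw  0.2045 0.1193   0.1562  0.0911     285                   18.8248
```

A 5 s head-rotation sweep at 114 Hz yields 570 pairs; half calibrate the
mapping, half evaluate it. The coefficients are over the standardized pupil
basis, so the intercept sits near the world-frame center (960, 540) and the
linear terms carry the px-per-px gain. Raw estimation leaves a mean error of
0.25 cm (0.19°) at 75 cm viewing distance; interpolating the calibration
residuals back onto the estimates reduces it, and the time-windowed variant
reduces it most — the ordering raw > IDW ≥ MIDW mirrors how the correction
behaves on real sessions.

The same pipeline is scriptable from the shell:

```sh
gazecal simulate --trajectory pursuit-rect --duration 4 --seed 42 --out session.csv
gazecal calibrate --pairs session.csv --seed 1 --model-out model.txt --residuals-out res.csv
gazecal evaluate  --session session.csv --seed 1 --report report.csv
gazecal map --model model.txt --points session.csv --kernel gaussian --bump --out map.png
```

`detect-pupil` and `detect-marker` run the detectors over directories of
image frames; `correct` applies IDW / windowed-IDW correction to estimated
points.

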
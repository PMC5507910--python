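# pcmri

Phase-contrast MRI (PC-MRI) encodes through-plane blood velocity in the
phase of the complex MR signal: a velocity *v* maps to a phase
φ = π·v/VENC, where VENC is the velocity-encoding limit. From a cine
series of magnitude/phase image pairs of a vessel cross-section one can
measure blood flow, lumen area and wall shear stress (WSS) — but in
small animals (a rat common carotid artery is only ~1 mm across) the
numbers depend strongly on how the scan is set up: cardiac gating,
the VENC choice (too low and the phase wraps), and in-plane resolution
(too coarse and partial-volume mixing inflates the apparent lumen while
flattening the wall velocity gradient).

`pcmri` is a small analysis toolkit for exactly this setting, for
researchers doing small-animal flow MRI or methods work on flow
quantification. It pairs:

- a **digital phantom** — a pulsatile cylindrical vessel with a
  near-parabolic profile in static tissue, forward-simulated as complex
  signal on a supersampled grid with box-averaging into acquisition
  pixels (the partial-volume mechanism), gated or cycle-averaged
  non-gated acquisition, background phase offsets, phase wrapping, and
  complex Gaussian noise — so every analysis stage can be validated
  against analytic ground truth;
- the **analysis chain**: phase→velocity conversion (v = φ·VENC/π),
  static-tissue polynomial background-offset correction, region-median
  velocity unwrapping, cubic B-spline lumen segmentation on the
  magnitude image, and quantification of flow (Σ v·dA), mean velocity,
  WSS = η·|dv/dr| at the wall (η = 3.5×10⁻³ N·s/m² for rat blood),
  lumen area, and the velocity-to-noise ratio
  VNR = v̄ / ((VENC/π)·√2/SNR);
- **study drivers** that replicate the two protocol-optimisation
  experiments at desk scale — gated vs non-gated across VENC 60–120 cm/s,
  and a resolution sweep 0.63/0.31/0.21/0.16 mm — with test–retest
  reproducibility summarised by the coefficient of variation
  CoVⱼ = (1/I)·Σᵢ SDₖ(xᵢⱼₖ)/meanₖ(xᵢⱼₖ).

For Poiseuille flow the closed forms Q = πR²·v_max/2 and
WSS = 2η·v_max/R anchor the whole chain.

## Worked example

```python
import numpy as np
from pcmri import PhantomSpec, default_acquisition, simulate_series, analyze_series

# steady Poiseuille vessel: R = 0.5 mm, centerline 60 cm/s, no noise
spec = PhantomSpec(v_systolic=60, v_diastolic=60, snr=np.inf)
params = default_acquisition(spec, venc=120, matrix_size=256)  # 0.16 mm grid
series = simulate_series(spec, params)
res = analyze_series(series)
print(f"flow {res.flow_ml_s:.4f} mL/s  area {res.area_mm2:.4f} mm^2  "
      f"wss {res.wss_n_m2:.3f} N/m^2")
```

prints

```
flow 0.2376 mL/s  area 0.8490 mm^2  wss 7.839 N/m^2
```

against the analytic 0.2356 mL/s, 0.7854 mm² and 8.4 N/m²: flow is
recovered to better than 1%, the area carries the expected small
positive bias of boundary-inclusive segmentation, and the wall shear
stress estimate sits within 7% of the analytic wall gradient.

The same pipeline is scriptable from the shell:

```sh
pcmri simulate --config phantom.json --out scan
pcmri segment --in scan --out contour.json
pcmri quantify --in scan --contour contour.json --out results.csv
pcmri study2 --subjects 12 --repeats 2 --seed 0 --out study2/
```

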
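"""End-to-end analysis of one PC-MRI series.

Chains the stages in the order the corrections require: phase-to-velocity
conversion, background offset removal (fitted on static tissue), lumen
segmentation on the temporal-mean magnitude, spline contour fit,
aliasing correction inside the lumen, and hemodynamic quantification.
"""

from __future__ import annotations

import numpy as np

from .hemo import (
    HemodynamicConfig,
    HemodynamicResult,
    compute_flow,
    compute_vnr,
    compute_wss,
    mean_velocity,
)
from .lumen import contour_to_mask, find_threshold, fit_contour, initial_mask
from .phantom import PCMRISeries
from .velocity import correct_background, fit_background, phase_to_velocity, unwrap_velocity

__all__ = ["analyze_series"]


def analyze_series(
    series: PCMRISeries,
    scan_id: str = "scan",
    repeat_index: int = 0,
    seed_point="auto",
    contour_points: int = 12,
    background_order: int = 1,
    unwrap: bool = True,
    hemo_cfg: HemodynamicConfig | None = None,
) -> HemodynamicResult:
    """Run the full velocity -> lumen -> hemodynamics chain on one scan."""
    params = series.params
    spacing = params.pixel_spacing

    vmap = phase_to_velocity(series)
    mag_mean = series.magnitude.mean(axis=0)
    threshold, _ = find_threshold(mag_mean, spacing, seed_point=seed_point)
    mask0 = initial_mask(series.magnitude, spacing, seed_point=seed_point)
    model = fit_background(vmap, series.magnitude, mask0, order=background_order)
    vmap = correct_background(vmap, model)

    contour = fit_contour(
        mask0,
        K=contour_points,
        pixel_spacing=spacing,
        image=mag_mean,
        level=threshold,
    )
    mask = contour_to_mask(contour, params)
    if unwrap:
        vmap = unwrap_velocity(vmap, mask)

    flow = compute_flow(vmap, mask)
    vel = mean_velocity(vmap, mask)
    wss = compute_wss(vmap, contour, hemo_cfg)
    vnr = compute_vnr(vmap, mask, series)

    return HemodynamicResult(
        scan_id=scan_id,
        gated=params.gated,
        venc_cm_s=params.venc,
        resolution_mm=spacing,
        flow_ml_s=flow.cycle_mean,
        mean_velocity_cm_s=vel.cycle_mean,
        wss_n_m2=wss.mean,
        area_mm2=contour.area_mm2,
        vnr=float(vnr.vnr),
        repeat_index=repeat_index,
        flow_per_frame=np.asarray(flow.per_frame),
        wss_per_ray_frame=wss.per_ray_frame,
    )
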
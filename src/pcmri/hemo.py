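"""Hemodynamic outcomes: blood flow, mean velocity, wall shear stress, VNR.

Flow is the velocity integral over the lumen mask; wall shear stress is
the Newtonian 1D estimate WSS = eta * |dv/dr| at the wall, with the
radial velocity gradient obtained per ray by fitting a low-order model
to intraluminal samples and evaluating its derivative at the contour
radius.  For Poiseuille flow with peak velocity v_max and radius R the
closed forms WSS = 2*eta*v_max/R and Q = pi*R^2*v_max/2 serve as
oracles.  Velocities are cm/s and lengths mm internally; the single
conversion to SI happens in the WSS formula (a gradient of 1 (cm/s)/mm
is 10 1/s).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, WSSError
from .lumen import LumenContour
from .phantom import PCMRISeries
from .velocity import VelocityMap

__all__ = [
    "HemodynamicConfig",
    "HemodynamicResult",
    "FrameSeries",
    "WSSResult",
    "VNRResult",
    "compute_flow",
    "mean_velocity",
    "compute_wss",
    "compute_vnr",
]

#: dynamic viscosity of rat blood, N s / m^2
DEFAULT_VISCOSITY = 3.5e-3


@dataclasses.dataclass(frozen=True)
class HemodynamicConfig:
    """Tunables of the wall shear stress estimator.

    ``wss_fit`` selects the radial model: ``"quadratic"`` fits
    v(r) = a + b r + c r^2 without pinning the wall velocity;
    ``"linear-wall-zero"`` fits v(r) = s (R - r) through zero at the wall.
    ``wall_guard_px`` excludes samples closer to the wall than this many
    pixels, where partial-volume mixing corrupts the velocity; the fitted
    model is extrapolated to the wall radius.  The quadratic model is
    only trusted when the guarded window spans at least
    ``min_quadratic_window_px`` pixels with ``min_quadratic_samples``
    samples — below that (a lumen a couple of pixels across) the
    extrapolated curvature is unstable and a linear fit is used instead.
    """

    viscosity_eta: float = DEFAULT_VISCOSITY
    n_rays: int = 36
    fit_inner_fraction: float = 0.4
    n_radial_samples: int = 20
    wss_fit: str = "quadratic"
    wall_guard_px: float = 0.75
    min_quadratic_samples: int = 6
    min_quadratic_window_px: float = 1.0

    def __post_init__(self) -> None:
        if self.viscosity_eta <= 0:
            raise ConfigurationError("viscosity must be positive")
        if self.n_rays < 8:
            raise ConfigurationError("need at least 8 rays")
        if not (0.0 < self.fit_inner_fraction < 1.0):
            raise ConfigurationError("fit_inner_fraction must lie in (0, 1)")
        if self.n_radial_samples < 4:
            raise ConfigurationError("need at least 4 radial samples")
        if self.wss_fit not in ("quadratic", "linear-wall-zero"):
            raise ConfigurationError(f"unknown wss_fit {self.wss_fit!r}")


class FrameSeries(NamedTuple):
    """A per-frame quantity with its cycle mean attached."""

    per_frame: np.ndarray
    cycle_mean: float


@dataclasses.dataclass
class WSSResult:
    """Wall shear stress per ray and frame with cycle/circumference averages."""

    per_ray_frame: np.ndarray  # frames x n_rays, N/m^2, NaN for dropped rays
    per_frame: np.ndarray  # circumference average per frame
    mean: float  # cycle- and circumference-averaged magnitude
    n_rays_dropped: int


@dataclasses.dataclass
class VNRResult:
    """Velocity-to-noise ratio with the quantities behind it."""

    vnr: float
    snr_magnitude: float
    sigma_v_cm_s: float
    mean_velocity_cm_s: float

    @property
    def infinite(self) -> bool:
        return np.isinf(self.vnr)


@dataclasses.dataclass
class HemodynamicResult:
    """All hemodynamic outcomes of one scan, ready for the results table."""

    scan_id: str
    gated: bool
    venc_cm_s: float
    resolution_mm: float
    flow_ml_s: float
    mean_velocity_cm_s: float
    wss_n_m2: float
    area_mm2: float
    vnr: float
    repeat_index: int = 0
    flow_per_frame: np.ndarray | None = None
    wss_per_ray_frame: np.ndarray | None = None

    def to_row(self) -> dict:
        return {
            "scan_id": self.scan_id,
            "gated": self.gated,
            "venc_cm_s": self.venc_cm_s,
            "resolution_mm": self.resolution_mm,
            "flow_ml_s": self.flow_ml_s,
            "mean_velocity_cm_s": self.mean_velocity_cm_s,
            "wss_n_m2": self.wss_n_m2,
            "area_mm2": self.area_mm2,
            "vnr": self.vnr,
            "repeat_index": self.repeat_index,
        }


def _check_mask(vmap: VelocityMap, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vmap.shape[1:]:
        raise ConfigurationError("mask grid does not match velocity grid")
    if not mask.any():
        raise DomainError("empty lumen mask")
    return mask


def compute_flow(
    vmap: VelocityMap, mask: np.ndarray, pixel_spacing: float | None = None
) -> FrameSeries:
    """Blood flow per frame in mL/s: sum of v * pixel area over the mask."""
    mask = _check_mask(vmap, mask)
    spacing = vmap.pixel_spacing if pixel_spacing is None else pixel_spacing
    pixel_area_cm2 = (spacing / 10.0) ** 2
    per_frame = vmap.velocity[:, mask].sum(axis=1) * pixel_area_cm2
    return FrameSeries(per_frame=per_frame, cycle_mean=float(per_frame.mean()))


def mean_velocity(vmap: VelocityMap, mask: np.ndarray) -> FrameSeries:
    """Arithmetic mean velocity (cm/s) over the lumen mask, per frame."""
    mask = _check_mask(vmap, mask)
    per_frame = vmap.velocity[:, mask].mean(axis=1)
    return FrameSeries(per_frame=per_frame, cycle_mean=float(per_frame.mean()))


def _wall_radius_by_angle(contour: LumenContour, angles: np.ndarray) -> np.ndarray:
    dense = contour.evaluate(512)
    cx, cy = contour.centroid
    theta = np.arctan2(dense[:, 1] - cy, dense[:, 0] - cx)
    radius = np.hypot(dense[:, 0] - cx, dense[:, 1] - cy)
    order = np.argsort(theta)
    theta_s, radius_s = theta[order], radius[order]
    theta_pad = np.concatenate([theta_s - 2 * np.pi, theta_s, theta_s + 2 * np.pi])
    radius_pad = np.concatenate([radius_s, radius_s, radius_s])
    return np.interp(angles, theta_pad, radius_pad)


def compute_wss(
    vmap: VelocityMap,
    contour: LumenContour,
    cfg: HemodynamicConfig | None = None,
) -> WSSResult:
    """Wall shear stress per ray and frame, eta * |dv/dr| at the wall.

    For each of ``n_rays`` directions from the contour centroid the wall
    radius R_theta is read off the contour; velocity is sampled by
    bilinear interpolation at ``n_radial_samples`` radii spanning
    [fit_inner_fraction * R_theta, R_theta].  Samples within
    ``wall_guard_px`` pixels of the wall are treated as partial-volume
    mixed and excluded; the fitted radial model is extrapolated to
    R_theta.  When the guard band would leave fewer than 4 samples (a
    lumen only one or two pixels across), the innermost 4 on-grid samples
    are used instead.  Rays with fewer than 4 on-grid samples are dropped;
    more than 25% dropped rays is an error.
    """
    cfg = cfg or HemodynamicConfig()
    cx, cy = contour.centroid
    spacing = vmap.pixel_spacing
    angles = 2.0 * np.pi * np.arange(cfg.n_rays) / cfg.n_rays
    wall_r = _wall_radius_by_angle(contour, angles)

    n_frames = vmap.n_frames
    wss = np.full((n_frames, cfg.n_rays), np.nan)
    rows, cols = vmap.shape[1:]
    dropped = 0
    for q, (theta, r_wall) in enumerate(zip(angles, wall_r)):
        radii = np.linspace(cfg.fit_inner_fraction * r_wall, r_wall, cfg.n_radial_samples)
        xs = cx + radii * np.cos(theta)
        ys = cy + radii * np.sin(theta)
        col_idx = xs / spacing - 0.5
        row_idx = ys / spacing - 0.5
        on_grid = (
            (row_idx >= 0) & (row_idx <= rows - 1) & (col_idx >= 0) & (col_idx <= cols - 1)
        )
        in_lumen = on_grid & (radii <= r_wall - cfg.wall_guard_px * spacing)
        if in_lumen.sum() < 4:
            # lumen too small for the guard band: keep the innermost samples
            candidates = np.nonzero(on_grid)[0][:4]
            in_lumen = np.zeros_like(on_grid)
            in_lumen[candidates] = True
        if in_lumen.sum() < 4:
            dropped += 1
            warnings.warn(
                f"ray {q} dropped: {int(in_lumen.sum())} usable samples",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        r_fit = radii[in_lumen]
        coords = np.vstack([row_idx[in_lumen], col_idx[in_lumen]])
        window = r_fit.max() - r_fit.min()
        quadratic_ok = (
            cfg.wss_fit == "quadratic"
            and in_lumen.sum() >= cfg.min_quadratic_samples
            and window >= cfg.min_quadratic_window_px * spacing
        )
        for t in range(n_frames):
            v_fit = ndimage.map_coordinates(
                vmap.velocity[t], coords, order=1, mode="nearest"
            )
            if cfg.wss_fit == "linear-wall-zero":
                basis = r_wall - r_fit
                s = float(basis @ v_fit / (basis @ basis))
                gradient = -s
            elif quadratic_ok:
                a, b, c = np.polynomial.polynomial.polyfit(r_fit, v_fit, 2)
                gradient = b + 2.0 * c * r_wall
            else:
                # unresolved wall region: stable first-order slope estimate
                b = np.polynomial.polynomial.polyfit(r_fit, v_fit, 1)[1]
                gradient = b
            # (cm/s)/mm -> 1/s requires a factor of 10
            wss[t, q] = cfg.viscosity_eta * abs(gradient) * 10.0

    if dropped > 0.25 * cfg.n_rays:
        raise WSSError(f"{dropped} of {cfg.n_rays} rays dropped (> 25%)")
    per_frame = np.nanmean(wss, axis=1)
    return WSSResult(
        per_ray_frame=wss,
        per_frame=per_frame,
        mean=float(per_frame.mean()),
        n_rays_dropped=dropped,
    )


def compute_vnr(
    vmap: VelocityMap,
    mask: np.ndarray,
    series: PCMRISeries,
    dilate_px: int = 3,
    background_decile: float = 10.0,
) -> VNRResult:
    """Velocity-to-noise ratio of the lumen mean velocity.

    The velocity noise is modelled as sigma_v = (venc/pi) * sqrt(2) / SNR
    where SNR is the magnitude signal-to-noise ratio: the blood signal
    over the noise SD measured in a background region.  The blood signal
    is the 90th percentile of the temporal-mean magnitude inside the
    lumen mask (robust against partial-volume-dimmed rim pixels); the
    background region is the lowest-intensity decile (by temporal-mean
    magnitude) outside the dilated lumen.  For multi-frame data the noise
    SD is the pooled within-pixel across-frame SD of that region, which
    is unbiased under the intensity-based region selection; a single
    non-gated frame falls back to the spatial SD (slightly low because of
    the selection).  A noiseless series yields an infinite VNR.
    """
    mask = _check_mask(vmap, mask)
    mag = series.magnitude
    mean_lumen_mag = float(np.percentile(mag.mean(axis=0)[mask], 90.0))
    outside = ~ndimage.binary_dilation(mask, iterations=max(dilate_px, 1))
    if not outside.any():
        raise DomainError("no background region outside the dilated lumen")
    mag_mean = mag.mean(axis=0)
    cutoff = np.percentile(mag_mean[outside], background_decile)
    region = outside & (mag_mean <= cutoff)
    values = mag[:, region]
    n_frames = values.shape[0]
    if n_frames >= 2:
        dev = values - values.mean(axis=0, keepdims=True)
        noise_sd = float(np.sqrt((dev**2).sum() / (values.shape[1] * (n_frames - 1))))
    else:
        noise_sd = float(values.std(ddof=1))
    v_mean = mean_velocity(vmap, mask).cycle_mean
    if noise_sd == 0.0:
        return VNRResult(
            vnr=np.inf, snr_magnitude=np.inf, sigma_v_cm_s=0.0, mean_velocity_cm_s=v_mean
        )
    snr = mean_lumen_mag / noise_sd
    sigma_v = (vmap.venc / np.pi) * np.sqrt(2.0) / snr
    return VNRResult(
        vnr=v_mean / sigma_v,
        snr_magnitude=snr,
        sigma_v_cm_s=sigma_v,
        mean_velocity_cm_s=v_mean,
    )
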
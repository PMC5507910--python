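"""Phase-to-velocity conversion and the two standard PC-MRI corrections.

Velocity maps use the convention v = phi * venc / pi, so a phase of pi
corresponds to the velocity-encoding limit.  Two corrections are applied
in a fixed order: (1) background phase-offset removal — a low-order
polynomial fitted over static tissue, the behavioural equivalent of
eddy-current / concomitant-gradient offset correction; (2) velocity
aliasing correction — a region-median unwrapping seeded from the region
boundary inward, adequate for single-vessel ROIs where aliasing occurs
at the vessel center while near-wall flow is slow.  Background first:
offset ramps can push near-VENC voxels across the wrap boundary.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DomainError, FittingError
from .phantom import PCMRISeries, pixel_centers

__all__ = [
    "VelocityMap",
    "BackgroundModel",
    "phase_to_velocity",
    "fit_background",
    "correct_background",
    "unwrap_velocity",
]


@dataclasses.dataclass
class VelocityMap:
    """Per-frame through-plane velocity field (cm/s) with correction state.

    ``wrap_count`` records, per voxel and frame, the number of 2*venc
    offsets added during aliasing correction (0 outside the unwrap ROI).
    """

    velocity: np.ndarray  # frames x rows x cols, cm/s
    venc: float
    pixel_spacing: float  # mm
    corrected_background: bool = False
    unwrapped: bool = False
    wrap_count: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.velocity.ndim != 3:
            raise ConfigurationError("velocity must be frames x rows x cols")
        if self.wrap_count is None:
            self.wrap_count = np.zeros(self.velocity.shape, dtype=np.int16)

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.velocity.shape


@dataclasses.dataclass
class BackgroundModel:
    """Fitted static-tissue velocity offset model.

    Coefficients are in velocity units: constant (cm/s), linear terms
    (cm/s per mm) and, for order 2, a radial-quadratic term
    (cm/s per mm^2) multiplying x^2 + y^2.
    """

    coeffs: np.ndarray
    static_mask: np.ndarray
    fit_residual_rms: float
    order: int
    shape: tuple[int, int]
    pixel_spacing: float

    def evaluate(self) -> np.ndarray:
        """Background velocity offset over the full image grid (cm/s)."""
        rows, cols = self.shape
        xs = pixel_centers(cols * self.pixel_spacing, cols)
        ys = pixel_centers(rows * self.pixel_spacing, rows)
        x, y = np.meshgrid(xs, ys)
        c = self.coeffs
        out = c[0] + c[1] * x + c[2] * y
        if self.order == 2:
            out = out + c[3] * (x**2 + y**2)
        return out


def phase_to_velocity(series: PCMRISeries) -> VelocityMap:
    """Convert wrapped phase images to a velocity map: v = phi * venc / pi."""
    venc = series.params.venc
    return VelocityMap(
        velocity=series.phase * venc / np.pi,
        venc=venc,
        pixel_spacing=series.params.pixel_spacing,
    )


def fit_background(
    vmap: VelocityMap,
    magnitude: np.ndarray,
    lumen_exclusion: np.ndarray,
    order: int = 1,
    magnitude_threshold: float = 0.2,
    sd_fraction: float = 0.05,
    dilate_px: int = 2,
    min_static_pixels: int = 200,
    min_fov_fraction: float = 0.05,
) -> BackgroundModel:
    """Fit a polynomial velocity offset over static tissue.

    The static mask keeps pixels with (a) temporal-mean magnitude above
    ``magnitude_threshold`` times the robust (99th percentile) maximum,
    (b) temporal velocity standard deviation below ``sd_fraction * venc``,
    and (c) outside the lumen mask dilated by ``dilate_px`` pixels.  The
    fit is ordinary least squares of the temporal-mean velocity on
    [1, x, y] (order 1) or [1, x, y, x^2 + y^2] (order 2), x/y in mm.
    """
    if order not in (1, 2):
        raise ConfigurationError("background order must be 1 or 2")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    mag_mean = magnitude.mean(axis=0) if magnitude.ndim == 3 else magnitude
    if mag_mean.shape != vmap.shape[1:]:
        raise ConfigurationError("magnitude grid does not match velocity grid")
    lumen_exclusion = np.asarray(lumen_exclusion, dtype=bool)
    if lumen_exclusion.shape != mag_mean.shape:
        raise ConfigurationError("lumen_exclusion grid does not match velocity grid")

    robust_max = np.percentile(mag_mean, 99.0)
    v = vmap.velocity
    temporal_sd = v.std(axis=0, ddof=0) if v.shape[0] > 1 else np.zeros(v.shape[1:])
    dilated = ndimage.binary_dilation(lumen_exclusion, iterations=max(dilate_px, 1))
    static = (
        (mag_mean > magnitude_threshold * robust_max)
        & (temporal_sd < sd_fraction * vmap.venc)
        & ~dilated
    )
    n_static = int(static.sum())
    n_total = static.size
    if n_static < min_static_pixels or n_static < min_fov_fraction * n_total:
        raise FittingError(
            f"too few static pixels for background fit: {n_static} of {n_total} "
            f"(need >= {min_static_pixels} and >= {min_fov_fraction:.0%} of FOV)"
        )

    rows, cols = mag_mean.shape
    xs = pixel_centers(cols * vmap.pixel_spacing, cols)
    ys = pixel_centers(rows * vmap.pixel_spacing, rows)
    x, y = np.meshgrid(xs, ys)
    v_mean = v.mean(axis=0)
    columns = [np.ones(n_static), x[static], y[static]]
    if order == 2:
        columns.append(x[static] ** 2 + y[static] ** 2)
    design = np.column_stack(columns)
    coeffs, _, _, _ = np.linalg.lstsq(design, v_mean[static], rcond=None)
    residual = v_mean[static] - design @ coeffs
    rms = float(np.sqrt(np.mean(residual**2)))
    if order == 1:
        coeffs = np.append(coeffs, 0.0)
    return BackgroundModel(
        coeffs=coeffs,
        static_mask=static,
        fit_residual_rms=rms,
        order=order,
        shape=mag_mean.shape,
        pixel_spacing=vmap.pixel_spacing,
    )


def correct_background(vmap: VelocityMap, model: BackgroundModel) -> VelocityMap:
    """Subtract the fitted background offset from every frame.

    Refuses to run twice on the same map (the correction flag is the
    idempotency contract) and refuses models fitted on a different grid.
    """
    if vmap.corrected_background:
        raise ConfigurationError("background correction already applied")
    if model.shape != vmap.shape[1:]:
        raise ConfigurationError(
            f"background model grid {model.shape} does not match velocity grid "
            f"{vmap.shape[1:]}"
        )
    corrected = vmap.velocity - model.evaluate()[np.newaxis, :, :]
    return dataclasses.replace(
        vmap,
        velocity=corrected,
        corrected_background=True,
        wrap_count=vmap.wrap_count.copy(),
    )


def _neighbor_values(v: np.ndarray, valid: np.ndarray, yy: int, xx: int) -> np.ndarray:
    y0, y1 = max(yy - 1, 0), min(yy + 2, v.shape[0])
    x0, x1 = max(xx - 1, 0), min(xx + 2, v.shape[1])
    sub_valid = valid[y0:y1, x0:x1].copy()
    sub_valid[yy - y0, xx - x0] = False
    return v[y0:y1, x0:x1][sub_valid]


def unwrap_velocity(vmap: VelocityMap, roi: np.ndarray, max_iter: int = 10) -> VelocityMap:
    """Correct velocity aliasing inside ``roi`` by region-median unwrapping.

    Voxels on the ROI boundary are assumed unwrapped in the seeding pass
    (slow near-wall flow); the correction proceeds inward: a voxel whose
    velocity differs from the median of its valid 8-neighborhood by more
    than venc is shifted by k * 2 * venc, k in {-1, +1}, whichever
    reduces the difference.  Relaxation sweeps over the whole ROI repeat
    until no voxel changes or ``max_iter`` sweeps have run (then a
    warning is raised and the partial result returned with
    ``converged=False``).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != vmap.shape[1:]:
        raise ConfigurationError("roi grid does not match velocity grid")
    if not roi.any():
        raise DomainError("unwrap roi is empty")

    venc = vmap.venc
    v = vmap.velocity.copy()
    wrap_count = vmap.wrap_count.copy()
    # chessboard distance to the ROI boundary: boundary ring has distance 1
    dist = ndimage.distance_transform_cdt(roi, metric="chessboard")
    inner_y, inner_x = np.nonzero(roi & (dist >= 2))
    order = np.lexsort((inner_x, inner_y, dist[inner_y, inner_x]))
    inner = list(zip(inner_y[order], inner_x[order]))
    all_y, all_x = np.nonzero(roi)
    order_all = np.lexsort((all_x, all_y, -dist[all_y, all_x]))
    everyone = list(zip(all_y[order_all], all_x[order_all]))
    converged = True

    def try_correct(vt, wt, yy, xx, valid) -> bool:
        vals = _neighbor_values(vt, valid, yy, xx)
        if vals.size == 0:
            return False
        med = float(np.median(vals))
        diff = vt[yy, xx] - med
        if abs(diff) <= venc:
            return False
        k = int(np.clip(np.round((med - vt[yy, xx]) / (2.0 * venc)), -1, 1))
        if k == 0 or abs(vt[yy, xx] + 2.0 * k * venc - med) >= abs(diff):
            return False
        vt[yy, xx] += 2.0 * k * venc
        wt[yy, xx] += k
        return True

    for t in range(vmap.n_frames):
        vt = v[t]
        wt = wrap_count[t]
        # seeding pass: only already-settled neighbors vote
        settled = roi & (dist == 1)
        for yy, xx in inner:
            try_correct(vt, wt, yy, xx, settled)
            settled[yy, xx] = True
        # relaxation passes over every ROI voxel (deepest first), so wrapped
        # voxels that happen to sit on the ROI boundary ring are still caught
        for _ in range(max_iter - 1):
            changed = False
            for yy, xx in everyone:
                changed |= try_correct(vt, wt, yy, xx, roi)
            if not changed:
                break
        else:
            converged = False
            warnings.warn(
                f"velocity unwrapping did not converge within {max_iter} sweeps "
                f"on frame {t}",
                RuntimeWarning,
                stacklevel=2,
            )

    return dataclasses.replace(
        vmap, velocity=v, wrap_count=wrap_count, unwrapped=True, converged=converged
    )
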
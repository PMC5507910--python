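"""On-disk formats: NIfTI image pairs with JSON sidecars, CSV result tables.

A series is stored as ``<prefix>_mag.nii.gz`` and ``<prefix>_phase.nii.gz``
(float32, phase in rad) plus ``<prefix>.json`` carrying the acquisition
parameters.  Arrays are stored with the time axis last (NIfTI convention)
and returned in frames x rows x cols order regardless of on-disk layout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, MetadataError
from .phantom import AcquisitionParams, PCMRISeries, wrap_phase

__all__ = ["SeriesBundle", "save_series", "load_series", "save_results", "load_results"]

RESULT_COLUMNS = [
    "scan_id",
    "gated",
    "venc_cm_s",
    "resolution_mm",
    "flow_ml_s",
    "mean_velocity_cm_s",
    "wss_n_m2",
    "area_mm2",
    "vnr",
    "repeat_index",
]

_SLICE_THICKNESS_MM = 2.0


@dataclasses.dataclass(frozen=True)
class SeriesBundle:
    """File locations of one stored PC-MRI series."""

    mag_path: Path
    phase_path: Path
    sidecar_path: Path
    checksum: str | None = None

    @classmethod
    def from_prefix(cls, prefix: str | Path) -> "SeriesBundle":
        prefix = Path(prefix)
        return cls(
            mag_path=prefix.parent / (prefix.name + "_mag.nii.gz"),
            phase_path=prefix.parent / (prefix.name + "_phase.nii.gz"),
            sidecar_path=prefix.parent / (prefix.name + ".json"),
        )


def _sha256(*paths: Path) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(p.read_bytes())
    return h.hexdigest()


def save_series(series: PCMRISeries, prefix: str | Path) -> SeriesBundle:
    """Write a series as two NIfTI files plus a JSON sidecar."""
    bundle = SeriesBundle.from_prefix(prefix)
    p = series.params
    affine = np.diag([p.pixel_spacing, p.pixel_spacing, _SLICE_THICKNESS_MM, 1.0])
    for arr, path in ((series.magnitude, bundle.mag_path), (series.phase, bundle.phase_path)):
        # frames x rows x cols -> rows x cols x 1 x frames
        data = np.moveaxis(arr, 0, -1)[:, :, np.newaxis, :].astype(np.float32)
        nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = {
        "venc_cm_s": p.venc,
        "fov_mm": p.fov,
        "matrix": p.matrix_size,
        "tr_ms": p.tr,
        "gated": p.gated,
        "gating_fraction": p.gating_fraction,
        "n_frames": p.n_frames,
        "nex": p.nex,
        "phase_units": "rad",
        "provenance": series.provenance,
    }
    bundle.sidecar_path.write_text(json.dumps(sidecar, indent=2, default=float))
    checksum = _sha256(bundle.mag_path, bundle.phase_path, bundle.sidecar_path)
    return dataclasses.replace(bundle, checksum=checksum)


def _load_nifti(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = data[:, :, 0, :] if data.shape[2] == 1 else data.reshape(data.shape[:2] + (-1,))
    elif data.ndim == 2:
        data = data[:, :, np.newaxis]
    elif data.ndim != 3:
        raise FormatError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")
    # rows x cols x frames -> frames x rows x cols
    data = np.moveaxis(data, -1, 0)
    spacing = float(img.header.get_zooms()[0])
    return data, spacing


def load_series(bundle: SeriesBundle | str | Path) -> PCMRISeries:
    """Load and validate a stored series.

    Phase images flagged as degrees by the sidecar ``phase_units`` field
    are converted to rad; phases are rewrapped into [-pi, pi).
    """
    if not isinstance(bundle, SeriesBundle):
        bundle = SeriesBundle.from_prefix(bundle)
    for path in (bundle.mag_path, bundle.phase_path, bundle.sidecar_path):
        if not Path(path).exists():
            raise FormatError(f"missing file: {path}")
    sidecar = json.loads(Path(bundle.sidecar_path).read_text())
    venc = sidecar.get("venc_cm_s")
    if venc is None or not venc > 0:
        raise MetadataError(f"sidecar venc_cm_s missing or non-positive: {venc!r}")

    magnitude, mag_spacing = _load_nifti(Path(bundle.mag_path))
    phase, _ = _load_nifti(Path(bundle.phase_path))
    if magnitude.shape != phase.shape:
        raise FormatError(
            f"magnitude shape {magnitude.shape} != phase shape {phase.shape}"
        )

    units = sidecar.get("phase_units", "rad")
    if units == "deg":
        phase = phase * np.pi / 180.0
    elif units != "rad":
        raise MetadataError(f"unknown phase_units {units!r}")
    phase = wrap_phase(phase)

    params = AcquisitionParams(
        venc=float(venc),
        fov=float(sidecar["fov_mm"]),
        matrix_size=int(sidecar["matrix"]),
        tr=float(sidecar["tr_ms"]),
        gated=bool(sidecar["gated"]),
        gating_fraction=float(sidecar.get("gating_fraction", 0.9)),
        n_frames=int(sidecar["n_frames"]),
        nex=int(sidecar.get("nex", 1)),
    )
    if abs(mag_spacing - params.pixel_spacing) > 1e-4:
        raise MetadataError(
            f"NIfTI pixel spacing {mag_spacing} inconsistent with sidecar "
            f"fov/matrix {params.pixel_spacing}"
        )
    provenance = sidecar.get("provenance", {})
    return PCMRISeries(magnitude=magnitude, phase=phase, params=params, provenance=provenance)


def save_results(results, path: str | Path) -> Path:
    """Write a table of per-scan hemodynamic results to CSV.

    ``results`` is a DataFrame or an iterable of mappings providing the
    columns ``scan_id, gated, venc_cm_s, resolution_mm, flow_ml_s,
    mean_velocity_cm_s, wss_n_m2, area_mm2, vnr, repeat_index``.
    Numbers are written with 8 significant digits.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(list(results))
    if results.empty:
        raise DomainError("refusing to write an empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise FormatError(f"results table missing columns: {missing}")
    path = Path(path)
    results[RESULT_COLUMNS].to_csv(path, index=False, float_format="%.8g")
    return path


def load_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`save_results`."""
    return pd.read_csv(path)
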
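"""Containers and on-disk formats for dynamic angiography data.

Every time-resolved series is held as a real-valued grid indexed
``(t, z, y, x)``; planar (projection) data simply has a z-extent of 1, so a
single code path serves both DSA-style image sequences and 4D CE-trMRA
volumes.  Times are seconds from acquisition start (frame ``k`` sits at
``k * dt``), coordinates are 0-based grid indices, and missing values in
derived marker maps are NaN.

Supported containers: 4D NIfTI-1 for series, 3D NIfTI-1 (+ JSON sidecar)
for marker maps and masks, and directories of equally shaped 2D TIFF/PNG
frames for projection sequences.  DICOM is out of scope; convert to NIfTI
first (e.g. with dcm2niix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "DynamicSeries",
    "VesselMask",
    "MarkerMap",
    "MARKER_KINDS",
    "load_dynamic_series",
    "write_dynamic_series",
    "write_marker_map",
    "load_marker_map",
    "write_vessel_mask",
    "load_vessel_mask",
]

MARKER_KINDS = ("toa", "toa_norm", "slope", "slope_norm")
MODALITY_TAGS = ("projection", "volumetric")

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DynamicSeries:
    """A time-resolved intensity grid c(i, t) with temporal spacing dt.

    Parameters
    ----------
    intensities
        Array of shape ``(t, z, y, x)`` of finite reals; planar data uses
        z-extent 1.
    dt
        Seconds per frame (> 0).
    spacing
        Voxel spacing ``(mm_z, mm_y, mm_x)``.
    injection_time
        Contrast-injection time in seconds relative to frame 0 (default 0;
        arrival times are reported relative to it).
    modality_tag
        ``"projection"`` (DSA-like) or ``"volumetric"`` (MRA-like); selects
        preprocessing defaults.
    background_subtracted
        Whether a pre-contrast mask frame has already been removed.
    """

    intensities: np.ndarray
    dt: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    injection_time: float = 0.0
    modality_tag: str = "volumetric"
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be (t, z, y, x); got ndim={self.intensities.ndim}"
            )
        if self.intensities.shape[0] < 2:
            raise ValueError("temporal extent < 2")
        if min(self.intensities.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive components (mm)")
        if self.modality_tag not in MODALITY_TAGS:
            raise ValueError(f"modality_tag must be one of {MODALITY_TAGS}")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    @property
    def frame_times(self) -> np.ndarray:
        """Seconds from acquisition start for every frame."""
        return np.arange(self.n_frames) * self.dt

    def with_intensities(self, intensities: np.ndarray, **changes) -> "DynamicSeries":
        """Copy of the series with new intensity data (same metadata)."""
        return replace(self, intensities=intensities, **changes)


@dataclass
class VesselMask:
    """Boolean spatial grid of voxels judged to carry contrast."""

    mask: np.ndarray
    threshold_used: float
    source_stat: str = "temporal_std"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be (z, y, x)")
        if not self.mask.any():
            raise ValueError("empty vessel mask: no voxel passes the threshold")
        if self.source_stat != "temporal_std":
            raise ValueError("source_stat must be 'temporal_std'")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MarkerMap:
    """Per-voxel scalar field for one hemodynamic marker.

    ``values`` is a ``(z, y, x)`` grid with NaN outside the vessel mask.
    ``context`` carries the normalization quantities (``toa_max`` and
    ``t_eff`` in seconds for toa_norm; ``si_max`` in 1/s for slope_norm).
    """

    values: np.ndarray
    kind: str
    dt: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (z, y, x)")
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"kind must be one of {MARKER_KINDS}")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        vals = self.present_values
        tol = 1e-9
        if vals.size:
            if self.kind in ("toa_norm", "slope_norm"):
                if vals.min() < -tol or vals.max() > 1 + tol:
                    raise ValueError(f"{self.kind} values must lie in [0, 1]")
            if self.kind == "toa_norm" and vals.min() > tol:
                raise ValueError("toa_norm: latest-arriving voxel must map to 0")
            if self.kind == "slope_norm" and abs(vals.max() - 1.0) > tol:
                raise ValueError("slope_norm: maximum present value must equal 1")

    @property
    def present(self) -> np.ndarray:
        """Boolean grid of voxels holding a value (inside mask, valid curve)."""
        return ~np.isnan(self.values)

    @property
    def present_values(self) -> np.ndarray:
        return self.values[self.present]

    def to_table(self):
        """Long-format (z, y, x, value) table of present voxels."""
        import pandas as pd

        z, y, x = np.nonzero(self.present)
        return pd.DataFrame(
            {"z": z, "y": y, "x": x, "value": self.values[z, y, x]}
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _load_frames(paths: Sequence[Path]) -> np.ndarray:
    import imageio.v3 as iio
    import tifffile

    frames = []
    for p in paths:
        if p.suffix.lower() in (".tif", ".tiff"):
            frame = tifffile.imread(p)
        else:
            frame = iio.imread(p)
        frame = np.asarray(frame, dtype=float)
        if frame.ndim == 3:  # RGB(A): collapse to luminance-free mean
            frame = frame.mean(axis=-1)
        if frame.ndim != 2:
            raise ValueError(f"frame {p.name} is not 2D")
        frames.append(frame)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    return np.stack(frames)[:, None, :, :]  # (t, 1, y, x)


def load_dynamic_series(
    path: str | Path, meta: Mapping | None = None
) -> DynamicSeries:
    """Read a dynamic series from 4D NIfTI or a directory of 2D frames.

    Frame files are taken in lexicographic (temporal) order.  ``meta``
    overrides/supplies ``dt``, ``spacing``, ``injection_time``,
    ``modality_tag``; for frame stacks ``dt`` is mandatory since image
    containers carry no temporal spacing.
    """
    meta = dict(meta or {})
    path = Path(path)

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames under {path}")
        if len(files) < 2:
            raise ValueError("temporal extent < 2")
        data = _load_frames(files)
        if "dt" not in meta:
            raise ValueError("dt is required for frame-stack input (supply via meta)")
        defaults = {"modality_tag": "projection"}
    else:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim == 3:  # (x, y, t) planar export
            arr = arr[:, :, None, :]
        if arr.ndim != 4:
            raise ValueError(f"expected 3D/4D NIfTI, got ndim={arr.ndim}")
        data = np.transpose(arr, (3, 2, 1, 0))  # (x,y,z,t) -> (t,z,y,x)
        zooms = img.header.get_zooms()
        defaults = {"modality_tag": "volumetric"}
        if len(zooms) >= 4 and zooms[3] > 0:
            defaults["dt"] = float(zooms[3])
        if len(zooms) >= 3:
            defaults["spacing"] = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        if "dt" not in meta and "dt" not in defaults:
            raise ValueError("dt missing from NIfTI header; supply via meta")

    kwargs = {**defaults, **meta}
    return DynamicSeries(intensities=data, **kwargs)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # spacing is (z, y, x); NIfTI stores (x, y, z)
    return np.diag([spacing[2], spacing[1], spacing[0], 1.0])


def write_dynamic_series(series: DynamicSeries, path: str | Path) -> None:
    """Write a series as 4D NIfTI; round-trips values, dt and spacing."""
    path = Path(path)
    arr = np.transpose(series.intensities, (3, 2, 1, 0))
    img = nib.Nifti1Image(arr.astype(np.float64), _affine(series.spacing))
    img.header.set_zooms(
        (series.spacing[2], series.spacing[1], series.spacing[0], series.dt)
    )
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {
        "dt": series.dt,
        "spacing": list(series.spacing),
        "injection_time": series.injection_time,
        "modality_tag": series.modality_tag,
        "background_subtracted": series.background_subtracted,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_marker_map(marker: MarkerMap, path: str | Path) -> None:
    """Write a marker map as 3D NIfTI (missing = NaN) plus a JSON sidecar."""
    if not marker.present.any():
        raise ValueError("empty marker map")
    path = Path(path)
    arr = np.transpose(marker.values, (2, 1, 0)).astype(np.float64)
    img = nib.Nifti1Image(arr, _affine(marker.spacing))
    img.header.set_zooms((marker.spacing[2], marker.spacing[1], marker.spacing[0]))
    nib.save(img, str(path))
    sidecar = {
        "kind": marker.kind,
        "dt": marker.dt,
        "spacing": list(marker.spacing),
        "context": marker.context,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_marker_map(path: str | Path) -> MarkerMap:
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=float)
    values = np.transpose(arr, (2, 1, 0))
    meta = json.loads(_sidecar_path(path).read_text())
    return MarkerMap(
        values=values,
        kind=meta["kind"],
        dt=meta["dt"],
        spacing=tuple(meta["spacing"]),
        context=meta.get("context", {}),
    )


def write_vessel_mask(
    mask: VesselMask, path: str | Path, spacing: tuple[float, float, float] = (1, 1, 1)
) -> None:
    path = Path(path)
    arr = np.transpose(mask.mask.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(arr, _affine(tuple(spacing)))
    nib.save(img, str(path))
    sidecar = {
        "threshold_used": mask.threshold_used,
        "source_stat": mask.source_stat,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_vessel_mask(path: str | Path) -> VesselMask:
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    meta = json.loads(_sidecar_path(path).read_text())
    return VesselMask(
        mask=np.transpose(arr, (2, 1, 0)) > 0,
        threshold_used=meta["threshold_used"],
        source_stat=meta.get("source_stat", "temporal_std"),
    )
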
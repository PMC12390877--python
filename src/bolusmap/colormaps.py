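"""Rendering of marker maps as 2D color overlays and 3D volume exports.

Color semantics follow the clinical reading of parametric angiography
maps: low arrival time (fast filling — feeding arteries, shunts) renders
red, high arrival time (draining veins) renders blue; the default
colormap is ``turbo_r``, a reversed perceptually ordered red-to-blue map.

For 3D-to-2D views the projection takes the extremal value along the ray:
the minimum for ``toa`` (earliest arrival dominates) and the maximum for
``toa_norm`` and the slope kinds (in those maps larger means earlier
arrival or steeper wash-in).  Rendering is a pure function of
(map, spec): identical inputs produce identical bytes, and marker values
are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from .io_formats import MarkerMap, write_marker_map

__all__ = ["RenderSpec", "render_2d", "export_3d"]

_UNITS = {"toa": "s", "toa_norm": "", "slope": "1/s", "slope_norm": ""}


@dataclass
class RenderSpec:
    colormap_name: str = "turbo_r"
    value_range: tuple[float, float] | None = None
    background: str = "black"
    projection_mode: str = "slice"

    def __post_init__(self) -> None:
        if self.value_range is not None:
            lo, hi = self.value_range
            if not lo < hi:
                raise ValueError("value_range must satisfy lo < hi")
        if self.background not in ("transparent", "black"):
            raise ValueError("background must be 'transparent' or 'black'")
        if self.projection_mode not in ("slice", "maximum_intensity"):
            raise ValueError("projection_mode must be 'slice' or 'maximum_intensity'")


def _project(values: np.ndarray, kind: str) -> np.ndarray:
    """Extremal projection along z, NaN where no voxel is present on a ray."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rays
        if kind == "toa":
            return np.nanmin(values, axis=0)
        return np.nanmax(values, axis=0)


def _slab(marker: MarkerMap, spec: RenderSpec, z_index: int | None) -> np.ndarray:
    if spec.projection_mode == "maximum_intensity":
        return _project(marker.values, marker.kind)
    z = 0 if z_index is None else int(z_index)
    if not 0 <= z < marker.values.shape[0]:
        raise ValueError(f"z_index {z} outside [0, {marker.values.shape[0]})")
    return marker.values[z]


def render_2d(
    marker: MarkerMap,
    spec: RenderSpec | None = None,
    z_index: int | None = None,
    path: str | Path | None = None,
) -> np.ndarray:
    """Render one slice (or an extremal z-projection) as a color image.

    Returns the 2D value slab actually rendered; when ``path`` is given a
    PNG with a unit-labelled color bar is written.  Missing voxels render
    as the background color.
    """
    if not marker.present.any():
        raise ValueError("empty marker map")
    spec = spec or RenderSpec()
    slab = _slab(marker, spec, z_index)
    if not np.isfinite(slab).any():
        warnings.warn("all-missing slice: rendering background only")
        lo, hi = 0.0, 1.0
    elif spec.value_range is not None:
        lo, hi = spec.value_range
    else:
        lo, hi = float(np.nanmin(slab)), float(np.nanmax(slab))
        if hi <= lo:
            hi = lo + 1.0

    if path is not None:
        cmap = plt.get_cmap(spec.colormap_name).copy()
        bg = (0, 0, 0, 0) if spec.background == "transparent" else "black"
        cmap.set_bad(bg)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            np.ma.masked_invalid(slab), cmap=cmap, vmin=lo, vmax=hi, origin="upper"
        )
        ax.set_axis_off()
        unit = _UNITS[marker.kind]
        label = marker.kind + (f" [{unit}]" if unit else "")
        fig.colorbar(im, ax=ax, label=label)
        fig.savefig(path, dpi=100, metadata={"Software": "bolusmap"})
        plt.close(fig)
    return slab


def export_3d(
    marker: MarkerMap,
    spec: RenderSpec | None = None,
    out_dir: str | Path = ".",
    angle_step: float = 10.0,
) -> list[Path]:
    """Export a volumetric map for external viewers plus rotating projections.

    Writes the masked scalar volume as NIfTI and a sequence of
    ``360 / angle_step`` extremal-projection frames (PNG), the volume
    rotated about the vertical image axis with nearest-neighbour sampling
    so projected values are actual marker values.
    """
    if marker.values.shape[0] < 2:
        raise ValueError("export_3d requires volumetric data")
    spec = spec or RenderSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_marker_map(marker, out_dir / f"{marker.kind}_volume.nii")

    # fill missing with the identity of the extremum so rotation padding
    # and absent voxels never win the projection
    minimizing = marker.kind == "toa"
    fill = np.inf if minimizing else -np.inf
    vol = np.where(np.isnan(marker.values), fill, marker.values)

    finite = marker.present_values
    lo, hi = float(finite.min()), float(finite.max())
    if spec.value_range is not None:
        lo, hi = spec.value_range
    if hi <= lo:
        hi = lo + 1.0

    cmap = plt.get_cmap(spec.colormap_name).copy()
    cmap.set_bad((0, 0, 0, 0) if spec.background == "transparent" else "black")

    n_frames = int(round(360.0 / angle_step))
    paths = []
    for i in range(n_frames):
        rot = ndimage.rotate(
            vol, i * angle_step, axes=(0, 2), reshape=True, order=0,
            mode="constant", cval=fill,
        )
        proj = rot.min(axis=0) if minimizing else rot.max(axis=0)
        proj = np.where(np.isfinite(proj), proj, np.nan)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(
            np.ma.masked_invalid(proj), cmap=cmap, vmin=lo, vmax=hi, origin="upper"
        )
        ax.set_axis_off()
        frame_path = out_dir / f"{marker.kind}_rot_{i:03d}.png"
        fig.savefig(frame_path, dpi=100, metadata={"Software": "bolusmap"})
        plt.close(fig)
        paths.append(frame_path)
    return paths
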
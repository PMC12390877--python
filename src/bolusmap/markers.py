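"""Hemodynamic markers of contrast transport.

Two per-voxel markers are computed from preprocessed time-intensity
curves:

* ``CA_ToA`` — time of arrival: seconds from injection until the curve
  first reaches 10% of its own peak.  Using the per-voxel peak (rather
  than the global maximum) keeps dim, diluted veins detectable; a
  ``reference="global"`` escape hatch applies 10% of the global maximum
  instead.
* ``CA_si`` — dispersive wash-in slope: the curve is first divided by its
  own peak I_max (dilution correction), then the maximum forward
  difference ``(c(t + dt) - c(t)) / dt`` is taken, in 1/s.

Normalized variants enable cross-acquisition comparison:
``toa_norm = (max_j ToA_j - ToA_i) / t_eff`` (latest arrival maps to 0,
earliest to the largest value) where ``t_eff`` is the total effective time
the contrast was present, and ``slope_norm = si_i / max_j si_j``.

Voxels inside the mask whose curve is identically zero (possible after
noise thresholding) are reported as missing, never as zero — zero would
read as instantaneous arrival.
"""

from __future__ import annotations

import numpy as np

from .io_formats import DynamicSeries, MarkerMap, VesselMask

__all__ = [
    "compute_toa",
    "effective_time",
    "normalize_toa",
    "compute_slope",
    "normalize_slope",
]


def _masked_curves(series: DynamicSeries, mask: VesselMask) -> np.ndarray:
    if mask.mask.shape != series.spatial_shape:
        raise ValueError("mask shape does not match the series spatial shape")
    return series.intensities[:, mask.mask]  # (T, N)


def _fill(mask: VesselMask, flat: np.ndarray) -> np.ndarray:
    out = np.full(mask.mask.shape, np.nan)
    out[mask.mask] = flat
    return out


def compute_toa(
    series: DynamicSeries,
    mask: VesselMask,
    fraction: float = 0.1,
    interpolate: bool = False,
    reference: str = "voxel",
) -> MarkerMap:
    """Per-voxel contrast time of arrival at the ``fraction``-of-peak crossing.

    Arrival is ``k * dt - injection_time`` where ``k`` is the first frame
    whose value reaches ``fraction`` of the voxel's peak (ties at the peak
    resolve to the first occurrence; the crossing search starts at frame 0).
    With ``interpolate=True`` the crossing is linearly interpolated between
    frames ``k - 1`` and ``k`` for sub-frame resolution (default off).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if reference not in ("voxel", "global"):
        raise ValueError("reference must be 'voxel' or 'global'")
    curves = _masked_curves(series, mask)
    peak = curves.max(axis=0)
    if reference == "global":
        thresh = np.full_like(peak, fraction * series.intensities.max())
    else:
        thresh = fraction * peak
    valid = peak > 0
    reached = curves >= thresh[None, :]
    # voxels that never reach the threshold (only possible with global ref)
    valid &= reached.any(axis=0)
    k = np.argmax(reached, axis=0).astype(float)
    if interpolate:
        for j in np.nonzero(valid)[0]:
            kk = int(k[j])
            if kk > 0:
                lo, hi = curves[kk - 1, j], curves[kk, j]
                if hi > lo:
                    k[j] = kk - 1 + (thresh[j] - lo) / (hi - lo)
    toa = k * series.dt - series.injection_time
    toa[~valid] = np.nan
    return MarkerMap(
        values=_fill(mask, toa),
        kind="toa",
        dt=series.dt,
        spacing=series.spacing,
        context={"fraction": fraction, "reference": reference},
    )


def effective_time(
    series: DynamicSeries, mask: VesselMask, fraction: float = 0.1
) -> float:
    """Total effective contrast-presence time over the mask.

    The span from the earliest to the latest frame time at which any masked
    voxel sits at or above ``fraction`` of its own peak.
    """
    curves = _masked_curves(series, mask)
    peak = curves.max(axis=0)
    valid = peak > 0
    if not valid.any():
        raise ValueError("no masked voxel carries signal")
    above = curves[:, valid] >= fraction * peak[valid]
    first = np.argmax(above, axis=0)
    last = above.shape[0] - 1 - np.argmax(above[::-1], axis=0)
    t_eff = (last.max() - first.min()) * series.dt
    if not t_eff > 0:
        raise ValueError("effective contrast time is zero (single-frame support)")
    return float(t_eff)


def normalize_toa(
    toa: MarkerMap,
    t_eff: float | None = None,
    series: DynamicSeries | None = None,
    mask: VesselMask | None = None,
    fraction: float = 0.1,
) -> MarkerMap:
    """Normalize arrival times: ``(max_j ToA_j - ToA_i) / t_eff``.

    The latest-arriving voxel maps to 0 and earlier voxels to larger
    values, which removes injection-timing offsets between acquisitions.
    When ``t_eff`` is not supplied it is derived from ``series``/``mask``
    as the above-10%-of-peak presence span (:func:`effective_time`); pass
    an acquisition-derived value to override.
    """
    if toa.kind != "toa":
        raise ValueError("normalize_toa expects a map of kind 'toa'")
    vals = toa.present_values
    if vals.size == 0:
        raise ValueError("all-missing arrival-time map")
    if t_eff is None:
        if series is None or mask is None:
            raise ValueError("supply t_eff or (series, mask) to derive it")
        t_eff = effective_time(series, mask, fraction)
    if not t_eff > 0:
        raise ValueError("t_eff must be > 0")
    toa_max = float(np.nanmax(toa.values))
    norm = (toa_max - toa.values) / t_eff
    if np.nanmax(norm) > 1 + 1e-9:
        raise ValueError("t_eff is smaller than the observed arrival-time span")
    return MarkerMap(
        values=norm,
        kind="toa_norm",
        dt=toa.dt,
        spacing=toa.spacing,
        context={"toa_max": toa_max, "t_eff": float(t_eff)},
    )


def compute_slope(series: DynamicSeries, mask: VesselMask) -> MarkerMap:
    """Maximum forward-difference slope of the dilution-corrected curve.

    Each masked voxel's curve is divided by its own peak (unit-peak,
    dilution-corrected curve) before taking
    ``max_t (c(t + dt) - c(t)) / dt``; the final frame contributes no
    difference.  Units: 1/s.
    """
    if series.n_frames < 2:
        raise ValueError("slope needs at least 2 frames")
    curves = _masked_curves(series, mask)
    peak = curves.max(axis=0)
    valid = peak > 0
    scaled = np.divide(
        curves, peak[None, :], out=np.zeros_like(curves),
        where=valid[None, :],
    )
    si = np.diff(scaled, axis=0).max(axis=0) / series.dt
    si[~valid] = np.nan
    return MarkerMap(
        values=_fill(mask, si),
        kind="slope",
        dt=series.dt,
        spacing=series.spacing,
    )


def normalize_slope(slope: MarkerMap) -> MarkerMap:
    """Divide slopes by the overall maximum so the map peaks at exactly 1."""
    if slope.kind != "slope":
        raise ValueError("normalize_slope expects a map of kind 'slope'")
    vals = slope.present_values
    if vals.size == 0:
        raise ValueError("all-missing slope map")
    si_max = float(np.nanmax(slope.values))
    if not si_max > 0:
        raise ValueError("maximum slope must be > 0 for normalization")
    return MarkerMap(
        values=slope.values / si_max,
        kind="slope_norm",
        dt=slope.dt,
        spacing=slope.spacing,
        context={"si_max": si_max},
    )
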
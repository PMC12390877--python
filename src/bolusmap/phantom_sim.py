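"""Synthetic dynamic-angiography phantom with known contrast kinetics.

The simulator rasterizes a small vascular tree — a feeding artery, a
nidus-like core and draining veins, mirroring the one-artery/two-vein
configuration typical of an extremity AVM — onto a voxel grid and drives
every segment with a gamma-variate first-pass bolus

    c(t) = A * ((t - t0) / (alpha * tau))**alpha * exp(alpha - (t - t0)/tau)

(zero for ``t <= t0``), which peaks at exactly ``A`` at ``t0 + alpha*tau``.
Dispersion grows downstream: each segment adds its ``onset_delay`` to the
bolus onset and its ``dispersion_tau`` to the bolus time constant.  An
optional delayed second-pass term per segment emulates late venous
drainage (the capillary-venulous AVM signature of arrival times far beyond
the arterial peak).

Acquisition effects are modelled as an optional Gaussian point-spread blur
(partial volume), additive zero-mean Gaussian noise (seeded) and clipping
of negatives; a z-sum projection twin of the same volume emulates a
DSA-style planar acquisition of the same geometry.  Ground truth (the
continuous 10%-of-peak crossing and the maximum unit-peak slope of each
noiseless, unblurred local curve) is carried alongside for
parameter-recovery tests.

Default acquisition regimes follow clinical practice: ~0.125 s frames on a
fine in-plane grid for the projection twin, ~1.1 s frames on a coarse 3D
grid for the volumetric one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .io_formats import DynamicSeries

__all__ = [
    "Bolus",
    "SecondPass",
    "Segment",
    "PhantomSpec",
    "PhantomTruth",
    "gamma_variate",
    "build_phantom",
    "simulate_series",
    "project_series",
    "default_phantom_spec",
    "late_drainage_spec",
    "twin_acquisition_specs",
]

SEGMENT_LABELS = ("artery", "nidus", "vein")

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gamma_variate(t, t0: float, alpha: float, tau: float, A: float):
    """Normalized gamma-variate bolus curve; peak value A at t0 + alpha*tau."""
    if not alpha > 0 or not tau > 0:
        raise ValueError("alpha and tau must be > 0")
    t = np.asarray(t, dtype=float)
    s = t - t0
    out = np.zeros_like(s)
    pos = s > 0
    sp = s[pos]
    out[pos] = A * (sp / (alpha * tau)) ** alpha * np.exp(alpha - sp / tau)
    return out if out.ndim else float(out)


def _gamma_derivative(t, t0, alpha, tau, A):
    """Analytic time derivative of :func:`gamma_variate` (zero for t <= t0)."""
    t = np.asarray(t, dtype=float)
    g = gamma_variate(t, t0, alpha, tau, A)
    s = t - t0
    out = np.zeros_like(g)
    pos = s > 0
    out[pos] = g[pos] * (alpha / s[pos] - 1.0 / tau)
    return out


@dataclass
class Bolus:
    """Injected bolus: onset t0 (s), shape alpha, time constant tau (s), peak A."""

    t0: float = 1.0
    alpha: float = 2.0
    tau: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0 or not self.tau > 0 or not self.amplitude > 0:
            raise ValueError("alpha, tau and amplitude must be > 0")


@dataclass
class SecondPass:
    """Delayed second bolus passage (recirculation / late venous drainage)."""

    delay: float
    amplitude: float
    tau_scale: float = 2.0

    def __post_init__(self) -> None:
        if not self.delay > 0 or not self.amplitude > 0 or not self.tau_scale > 0:
            raise ValueError("delay, amplitude and tau_scale must be > 0")


@dataclass
class Segment:
    """Axis-aligned box region with segment-specific bolus modification.

    ``box`` is ``((z0, z1), (y0, y1), (x0, x1))`` half-open index ranges.
    The segment's curve is ``amplitude_scale`` times the bolus delayed by
    ``onset_delay`` and broadened by ``dispersion_tau``, plus the optional
    ``second_pass`` term.
    """

    label: str
    box: tuple
    onset_delay: float = 0.0
    dispersion_tau: float = 0.0
    amplitude_scale: float = 1.0
    second_pass: SecondPass | None = None

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"label must be one of {SEGMENT_LABELS}")
        if len(self.box) != 3 or any(hi <= lo for lo, hi in self.box):
            raise ValueError("box must be three nonempty (lo, hi) ranges")
        if self.onset_delay < 0 or self.dispersion_tau < 0:
            raise ValueError("onset_delay and dispersion_tau must be >= 0")
        if not self.amplitude_scale > 0:
            raise ValueError("amplitude_scale must be > 0")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(int(lo), int(hi)) for lo, hi in self.box)

    def terms(self, bolus: Bolus) -> list[tuple[float, float, float, float]]:
        """(t0, alpha, tau, A) gamma terms composing this segment's curve."""
        t0 = bolus.t0 + self.onset_delay
        tau = bolus.tau + self.dispersion_tau
        terms = [(t0, bolus.alpha, tau, self.amplitude_scale * bolus.amplitude)]
        if self.second_pass is not None:
            sp = self.second_pass
            terms.append(
                (t0 + sp.delay, bolus.alpha, tau * sp.tau_scale,
                 sp.amplitude * bolus.amplitude)
            )
        return terms

    def curve(self, t, bolus: Bolus):
        t = np.asarray(t, dtype=float)
        return sum(gamma_variate(t, *term) for term in self.terms(bolus))

    def curve_derivative(self, t, bolus: Bolus):
        t = np.asarray(t, dtype=float)
        return sum(_gamma_derivative(t, *term) for term in self.terms(bolus))


@dataclass
class PhantomSpec:
    """Full description of one simulated acquisition."""

    grid_shape: tuple[int, int, int]
    dt: float
    n_frames: int
    segments: list[Segment]
    bolus: Bolus = field(default_factory=Bolus)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.0
    psf_fwhm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be three positive extents")
        if not self.dt > 0 or self.n_frames < 2:
            raise ValueError("need dt > 0 and n_frames >= 2")
        if not self.segments:
            raise ValueError("at least one segment required")
        if self.noise_sd < 0 or self.psf_fwhm < 0:
            raise ValueError("noise_sd and psf_fwhm must be >= 0")
        window = self.n_frames * self.dt
        for seg in self.segments:
            for t0, _, tau, _ in seg.terms(self.bolus):
                if window <= t0 + 5.0 * tau:
                    raise ValueError(
                        f"acquisition window {window:g}s too short for segment "
                        f"'{seg.label}' (needs > {t0 + 5 * tau:g}s)"
                    )
        occupancy = np.zeros(self.grid_shape, dtype=int)
        for seg in self.segments:
            sl = seg.slices()
            sub = occupancy[sl]
            if sub.size == 0:
                raise ValueError(f"segment '{seg.label}' lies outside the grid")
            sub += 1
        if occupancy.max() > 1:
            raise ValueError("segments must be spatially disjoint")

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class PhantomTruth:
    """Ground truth on voxels with a nonzero noiseless curve (NaN elsewhere)."""

    true_toa: np.ndarray
    true_si: np.ndarray
    labels: np.ndarray  # segment label per voxel, '' for background

    def label_mask(self, label: str) -> np.ndarray:
        return self.labels == label


def build_phantom(spec: PhantomSpec):
    """Rasterize segments: (label volume, per-segment kinetic parameters).

    Returns the string label grid and a list of ``(segment, slices)``
    pairs; each voxel inherits its segment's delayed onset and broadened
    time constant.
    """
    labels = np.full(spec.grid_shape, "", dtype="<U8")
    placed = []
    for seg in spec.segments:
        sl = seg.slices()
        labels[sl] = seg.label
        placed.append((seg, sl))
    return labels, placed


def _continuous_toa(seg: Segment, bolus: Bolus, window: float, fraction: float = 0.1):
    """First continuous time the noiseless curve reaches fraction*peak."""
    t = np.linspace(0.0, window, 4001)
    c = seg.curve(t, bolus)
    peak = c.max()
    target = fraction * peak
    above = c >= target
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    f = lambda x: seg.curve(x, bolus) - target
    return float(brentq(f, t[i - 1], t[i], xtol=1e-12))


def _max_unit_slope(seg: Segment, bolus: Bolus, window: float) -> float:
    """Maximum derivative of the unit-peak (dilution-corrected) curve, 1/s."""
    t = np.linspace(0.0, window, 8001)
    peak = seg.curve(t, bolus).max()
    return float(seg.curve_derivative(t, bolus).max() / peak)


def simulate_series(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[DynamicSeries, PhantomTruth]:
    """Simulate one volumetric acquisition of the phantom.

    Per voxel the segment curve is evaluated at the frame times; the
    volume is then blurred by the optional Gaussian PSF, Gaussian noise of
    sd ``noise_sd`` is added (seeded via ``spec.seed`` unless ``rng`` is
    given) and negatives are clipped to 0.  Truth is computed on the
    pre-blur, pre-noise curves.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    t = spec.frame_times
    window = spec.n_frames * spec.dt
    vol = np.zeros((spec.n_frames, *spec.grid_shape))
    true_toa = np.full(spec.grid_shape, np.nan)
    true_si = np.full(spec.grid_shape, np.nan)
    labels, placed = build_phantom(spec)
    for seg, sl in placed:
        curve = seg.curve(t, spec.bolus)
        vol[(slice(None), *sl)] = curve[:, None, None, None]
        true_toa[sl] = _continuous_toa(seg, spec.bolus, window)
        true_si[sl] = _max_unit_slope(seg, spec.bolus, window)
    if spec.psf_fwhm > 0:
        sigma = [spec.psf_fwhm * _FWHM_TO_SIGMA / s for s in spec.spacing]
        for k in range(spec.n_frames):
            vol[k] = ndimage.gaussian_filter(vol[k], sigma=sigma)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    np.clip(vol, 0.0, None, out=vol)
    series = DynamicSeries(
        intensities=vol,
        dt=spec.dt,
        spacing=spec.spacing,
        modality_tag="volumetric",
    )
    return series, PhantomTruth(true_toa=true_toa, true_si=true_si, labels=labels)


def project_series(series: DynamicSeries) -> DynamicSeries:
    """z-sum projection twin of a volumetric series (idealized DSA geometry)."""
    proj = series.intensities.sum(axis=1, keepdims=True)
    return DynamicSeries(
        intensities=proj,
        dt=series.dt,
        spacing=series.spacing,
        injection_time=series.injection_time,
        modality_tag="projection",
        background_subtracted=series.background_subtracted,
    )


# ---------------------------------------------------------------------------
# study geometries
# ---------------------------------------------------------------------------

def _tree_segments(scale: int = 1) -> list[Segment]:
    """Artery -> nidus -> two draining veins with staggered onsets.

    Onsets increase downstream (artery 0 s, nidus 2 s, veins 4/5 s) and so
    does dispersion (0, 1, 2 s added to the bolus time constant), the
    qualitative behaviour of a bolus traversing an AVM.
    """
    s = scale

    def box(z, y, x):
        return (tuple(v * s for v in z), tuple(v * s for v in y), tuple(v * s for v in x))

    return [
        Segment("artery", box((0, 4), (4, 12), (2, 46)), 0.0, 0.0),
        Segment("nidus", box((0, 4), (16, 36), (8, 40)), 2.0, 1.0),
        Segment("vein", box((0, 4), (40, 46), (4, 22)), 4.0, 2.0),
        Segment("vein", box((0, 4), (40, 46), (26, 44)), 5.0, 2.0),
    ]


def default_phantom_spec(
    dt: float = 0.5,
    n_frames: int = 120,
    noise_sd: float = 0.0,
    seed: int = 0,
    psf_fwhm: float = 0.0,
) -> PhantomSpec:
    """Reference 3-segment phantom: 4x56x56 grid, 0.5 s frames, 60 s window."""
    return PhantomSpec(
        grid_shape=(4, 56, 56),
        dt=dt,
        n_frames=n_frames,
        segments=_tree_segments(),
        noise_sd=noise_sd,
        psf_fwhm=psf_fwhm,
        seed=seed,
    )


def late_drainage_spec(
    dt: float = 1.1, n_frames: int = 72, noise_sd: float = 0.0, seed: int = 0
) -> PhantomSpec:
    """Phantom with a late second-pass venous compartment.

    The vein segments carry a weak first pass (heavy dilution) and a
    dominant second pass delayed by ~20 s, so their 10%-of-peak arrival
    falls far beyond the arterial peak — the late-venous-drainage
    signature of capillary-venulous AVMs.
    """
    segments = [
        Segment("artery", ((0, 4), (4, 12), (2, 46)), 0.0, 0.0),
        Segment("nidus", ((0, 4), (16, 36), (8, 40)), 2.0, 1.0),
        Segment(
            "vein", ((0, 4), (40, 46), (4, 22)), 2.0, 1.0,
            amplitude_scale=0.04, second_pass=SecondPass(delay=20.0, amplitude=1.0),
        ),
        Segment(
            "vein", ((0, 4), (40, 46), (26, 44)), 2.0, 1.0,
            amplitude_scale=0.04, second_pass=SecondPass(delay=24.0, amplitude=1.0),
        ),
    ]
    return PhantomSpec(
        grid_shape=(4, 56, 56),
        dt=dt,
        n_frames=n_frames,
        segments=segments,
        noise_sd=noise_sd,
        seed=seed,
    )


def _coarsen_segment(seg: Segment, factor: int) -> Segment:
    box = tuple((lo // factor, max(lo // factor + 1, hi // factor)) for lo, hi in seg.box)
    return replace(seg, box=box)


def twin_acquisition_specs(
    seed: int = 0,
    noise_sd: float = 0.05,
    dsa_dt: float = 0.125,
    mra_dt: float = 1.1,
) -> tuple[PhantomSpec, PhantomSpec]:
    """Same tree imaged under the two clinical regimes.

    Returns (fine projection-destined spec, coarse volumetric spec): the
    first samples a fine 6x32x32 grid at DSA-like 0.125 s frames (to be
    z-summed via :func:`project_series`), the second the half-resolution
    grid at MRA-like 1.1 s frames with a partial-volume blur.
    """
    fine_segments = [
        Segment("artery", ((0, 6), (4, 8), (2, 30)), 0.0, 0.0),
        Segment("nidus", ((0, 6), (12, 22), (8, 24)), 2.0, 1.0),
        Segment("vein", ((0, 6), (26, 30), (2, 14)), 4.0, 2.0),
        Segment("vein", ((0, 6), (26, 30), (18, 30)), 5.0, 2.0),
    ]
    window_needed = 22.0  # latest onset + bolus t0 + 5 * broadest tau
    dsa = PhantomSpec(
        grid_shape=(6, 32, 32),
        dt=dsa_dt,
        n_frames=int(np.ceil(window_needed / dsa_dt)) + 2,
        segments=fine_segments,
        spacing=(1.4, 1.0, 1.0),
        noise_sd=noise_sd,
        seed=seed,
    )
    mra = PhantomSpec(
        grid_shape=(3, 16, 16),
        dt=mra_dt,
        n_frames=int(np.ceil(window_needed / mra_dt)) + 2,
        segments=[_coarsen_segment(s, 2) for s in fine_segments],
        spacing=(2.8, 2.0, 2.0),
        noise_sd=noise_sd,
        psf_fwhm=2.5,
        seed=seed + 1,
    )
    return dsa, mra
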
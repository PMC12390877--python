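# Methods

## Data model

All series are held as `(t, z, y, x)` grids of finite reals; planar
projection data (DSA-like) is the `z = 1` special case, so one marker
implementation serves both modalities.  Frame *k* sits at `k·dt` seconds
from acquisition start; coordinates are 0-based grid indices;
`injection_time` (default 0) only offsets reported arrival times.  Missing
marker values are NaN everywhere, including serialized NIfTI maps.

## Preprocessing

Fixed stage order: background subtraction (projection data only; the
pre-injection frame is removed from every frame, sign-flipped first for
negative-contrast polarity, negatives clipped to 0 because the markers are
defined on nonnegative wash-in curves) → optional crop → 1D temporal
median filter → 2D in-plane median filter → global min–max normalization →
noise threshold.  Whether to crop before or after filtering is not
determined by the problem; the fixed order keeps runs comparable.

Defaults per modality follow the respective acquisition characteristics:
volumetric data uses a 5-frame temporal window and a 2×2 in-plane kernel
(coarse grids, smoother noise), projection data 3 frames and 6×6 (fine
grids, spikier noise).  Both filters use edge-inclusive mirror padding;
boundary padding is otherwise a free choice, and mirroring avoids edge
darkening that would bias arrival times at the field-of-view border.  For
even kernel lengths the output pixel sits at offset `(k−1)//2` inside the
window and the median of an even count is the mean of the two middle order
statistics — a fixed convention so results are deterministic and checkable
against exhaustive oracles (scipy's even-size median takes the upper order
statistic instead, which is why the spatial filter is implemented
directly).  The noise threshold zeroes intensities below a fraction
(default 0.08, sensible range 0.07–0.10) of the *global* maximum,
consistent with the global normalization; spatial filtering is strictly
in-plane per z-slice, never 3D.

## Vessel detection

Per-voxel sample standard deviation over time (divisor T−1) separates
contrast-carrying voxels from static background.  Clinically the threshold
is tuned per patient in an absolute intensity scale (range 2.7–3.4);
absolute values are meaningless after arbitrary normalization, so here the
threshold multiplies a robust noise scale: the median absolute deviation
of the std population about its median, divided by 0.6745.  This keeps the
2.7–3.4 range meaningful across inputs and makes the mask invariant to
global rescaling.  When the MAD degenerates to zero (noiseless background
that is exactly constant) a tiny multiple of the largest std is used, so
every voxel with any temporal variation is kept and scale invariance is
preserved.  An empty mask raises a dedicated error advising a lower
threshold.

## Markers

`CA_ToA` uses the first frame whose value reaches 10% of the **per-voxel**
peak.  A global-maximum threshold would make dim, diluted veins
unreachable, and the dilution correction of the slope marker already
establishes the per-voxel peak as the reference scale; a
`reference="global"` escape hatch is provided.  Ties at the peak resolve
to the first occurrence; optional sub-frame linear interpolation between
the bracketing frames is off by default.  Masked voxels whose preprocessed
curve is identically zero (possible after noise thresholding) are reported
missing, never zero — zero would read as instantaneous arrival.

`t_eff`, the total effective contrast-presence time used to normalize
arrival times, has no canonical formula; it is operationalized as the span
from the earliest to the latest time any masked voxel sits at or above 10%
of its own peak, and can be overridden with an acquisition-derived value.
An explicit `t_eff` smaller than the observed arrival span is rejected
rather than producing normalized values above 1.

`CA_si` takes the forward (not central) difference of the unit-peak curve,
matching the marker's defining equation; the final frame contributes no
difference.  The forward difference underestimates the continuous maximum
slope by up to `max|ĉ''|·dt`, which is the tolerance used in the recovery
tests; this sensitivity to temporal resolution is inherent to the marker.

## Statistics

Histograms: arrival times bin at width `dt` from 0 (histogram shape then
reflects the acquisition's native temporal resolution); normalized markers
use 20 equal bins on [0, 1] (enough to resolve single- vs double-peak
shapes at realistic mask sizes); slopes use 20 bins on [0, max].  Values
equal to the top edge land in the last bin.

Moments (mean, median, skewness, kurtosis) are computed on the raw
per-voxel values, not binned frequencies, with population (divisor n)
conventions: Fisher–Pearson skewness `m3/m2^1.5` and non-excess kurtosis
`m4/m2²` (normal ≈ 3).

Histogram comparison uses a symmetric frequency-based χ²,
`Σ (fa − fb)²/(fa + fb)` over occupied bins after rebinning both
histograms onto a common grid (union range, overlap-proportional mass
reassignment), with `df = occupied bins − 1` (forced ≥ 1) and an
upper-tail p-value.  Working on normalized frequencies rather than counts
makes the statistic a distribution-shape distance that is insensitive to
mask size; this is one defensible reading of a χ² histogram test — the
exact binning/df conventions of such tests vary — so a goodness-of-fit
mode (`method="gof"`, second histogram as the expected distribution) is
also provided.

## Rendering

Low arrival time renders red, high blue (reversed `turbo`); 3D→2D
projections take the minimum along the ray for `toa` and the maximum for
`toa_norm` and the slope kinds, so the earliest arrival / steepest wash-in
dominates the view.  Volume exports write the masked scalar NIfTI plus a
rotating extremal-projection PNG sequence (default 36 frames at 10°),
using nearest-neighbour rotation so projected values are actual marker
values.  Rendering never alters marker data.

## Phantom simulator

Segments are axis-aligned boxes labelled artery/nidus/vein — a deliberate
geometric idealization of the one-feeder/nidus/two-drainers topology of an
extremity AVM.  Every segment shares one gamma-variate bolus
`c(t) = A·((t−t0)/(ατ))^α · exp(α − (t−t0)/τ)` (peak exactly `A` at
`t0 + ατ`), the standard first-pass kinetic model, modified downstream:
`onset_delay` adds to `t0` and `dispersion_tau` to `τ`, so the bolus
arrives later and more dispersed from artery to veins.  An optional
delayed second-pass term per segment emulates late venous drainage: with a
weak first pass (amplitude scale 0.04) and a dominant second pass ~20 s
later, the 10%-of-peak arrival of venous voxels falls far beyond the
arterial peak — the capillary-venulous-AVM signature.

Acquisition effects: optional Gaussian PSF blur (FWHM in mm, partial
volume), additive zero-mean Gaussian noise (all randomness flows from one
seed), clipping of negatives.  A z-sum of the volume provides a
projection-mode twin — a deliberate idealization of cone-beam projection
geometry.  Ground truth (continuous 10%-of-peak crossing; maximum
derivative of the unit-peak curve) is computed from the analytic curve on
a dense grid with Brent refinement of the bracketed crossing, on the
pre-blur, pre-noise curves.

Reference study conditions, chosen once:

- recovery phantom: 4×56×56 grid, dt 0.5 s, 120 frames (60 s window),
  onsets 0/2/4/5 s, dispersion 0/1/2/2 s; vessels occupy ~39% of the grid
  so the background mode dominates the robust noise scale.  Noisy variant
  at SNR 20 (`noise_sd = 0.05` against unit bolus amplitude, a realistic
  angiographic regime).
- twin acquisition: the same tree on a fine 6×32×32 grid at 0.125 s frames
  (z-summed, DSA regime) and on the half-resolution grid at 1.1 s frames
  with 2.5 mm FWHM blur (MRA regime) — frame intervals follow the two
  clinical acquisition protocols.

The simulator emulates staggered, dispersed bolus transport with
acquisition noise and partial volume; it does **not** model flow pulsatility,
recirculation mixing, MR signal physics (T1 saturation, flip-angle
response), X-ray attenuation, or motion.  Passing recovery tests therefore
demonstrates correctness of the marker computations under known kinetics,
not clinical performance on patient data.

## Numerical choices and edge cases

- Noiseless recovery: arrival-time error ≤ dt at every masked voxel; slope
  error within `max(5%, max|ĉ''|·dt)` of the dense-grid continuous
  maximum (the forward-difference discretization bound).
- Noise clipping makes pre-onset background half-Gaussian; its pooled sd
  is `noise_sd · sqrt(1/2 − 1/2π) ≈ 0.584·noise_sd`, the value the
  simulator's noise test checks.
- Degenerate inputs raise rather than guess: constant series at
  normalization, zero-variance samples at moment computation, empty masks
  and all-missing maps everywhere.
- Reruns with identical config and seed are byte-identical, including
  rendered PNGs (Agg backend, fixed metadata).

## Problem sizes

Test and acceptance runs use the reference conditions above: 10 noisy
replicates for recovery/Dice, 100 (tests) or 50 (acceptance script)
twin-acquisition replicates, 2·10³–10⁵-sample oracles for the statistical
conventions.  These sizes give stable rates (binomial sd of the twin
agreement rate at p≈1 is ≪ the 90% acceptance margin) while a full suite
run stays under a minute on one core.
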
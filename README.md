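# bolusmap

Contrast-bolus transport markers for dynamic angiography of peripheral
arterio-venous malformations (pAVMs).

A pAVM is a direct artery-to-vein shunt (often through a tangle of abnormal
vessels, the *nidus*) whose hemodynamics — fast arterial shunting, delayed
and dispersed venous drainage — are visible in how an injected contrast
agent (CA) washes through the lesion on time-resolved imaging.  `bolusmap`
turns a dynamic image series (2D+t DSA-style frame sequences or 3D+t
CE-trMRA volumes) into per-pixel/voxel hemodynamic markers, colormaps and
histogram summaries that characterize the lesion type, for researchers
working on image-based classification of vascular malformations.

## Markers

For each vessel voxel *i* with time-intensity curve *c(i, t)* sampled every
Δt seconds:

- **Time of arrival** — `CA_ToA(i)`: the time from injection until
  *c(i, t)* first reaches 10% of its own peak.  Normalized variant
  `CA_ToA_norm(i) = (max_j CA_ToA(j) − CA_ToA(i)) / t_eff`, where `t_eff`
  is the total effective time the CA is present; the latest-arriving voxel
  maps to 0, which removes injection-timing offsets between acquisitions.
- **Dispersive wash-in slope** — the curve is first divided by its own peak
  `I_max(i)` (dilution correction), then
  `CA_si(i) = max_t (ĉ(i, t + Δt) − ĉ(i, t)) / Δt` in s⁻¹.  Normalized:
  `CA_si_norm(i) = CA_si(i) / max_j CA_si(j)`.

Upstream of the markers: background subtraction (projection data), cropping,
1D temporal and 2D in-plane median filtering, global min–max normalization,
a noise threshold (default 8% of the global maximum), and vessel detection
by thresholding the per-voxel temporal standard deviation at `θ ×` a robust
noise scale (default θ = 3.0, tuning range 2.7–3.4).

Because no clinical data ship with the package, a phantom simulator
(`bolusmap.phantom_sim`) rasterizes an artery → nidus → veins tree driven
by gamma-variate bolus kinetics with known continuous ground truth, under
DSA-like (0.125 s frames, fine grid, z-sum projection) and MRA-like
(1.1 s frames, coarse blurred grid) acquisition regimes.

## Worked example

```python
import numpy as np
from bolusmap import (default_phantom_spec, simulate_series, run_preprocess,
                      temporal_std_map, detect_vessels, compute_markers,
                      histogram_metrics)

spec = default_phantom_spec(noise_sd=0.05, seed=7)   # SNR 20 phantom
series, truth = simulate_series(spec)
pre = run_preprocess(series)
mask = detect_vessels(temporal_std_map(pre), threshold=3.0)
maps = compute_markers(pre, mask)

print(f"mask voxels: {mask.n_voxels}")
m = histogram_metrics(maps["toa"])
print(f"CA_ToA  mean={m.mean:.2f} s  median={m.median:.2f} s  "
      f"skewness={m.skewness:.2f}  kurtosis={m.kurtosis:.2f}")
for lab in ("artery", "nidus", "vein"):
    med = np.nanmedian(maps["toa"].values[truth.labels == lab])
    print(f"median CA_ToA {lab}: {med:.2f} s")
```

prints

```
mask voxels: 5394
CA_ToA  mean=3.66 s  median=4.00 s  skewness=0.43  kurtosis=2.42
median CA_ToA artery: 1.50 s
median CA_ToA nidus: 4.00 s
median CA_ToA vein: 6.50 s
```

The mask covers the simulated tree (5394 voxels against 4832 true vessel
voxels plus a one-voxel partial-volume rim), and median arrival times
reproduce the downstream ordering artery < nidus < vein imposed by the
phantom's staggered onsets — the hemodynamic signature the markers are
designed to expose.  Kurtosis is non-excess (a normal sample prints ≈ 3).

The same pipeline is available from the shell:

```sh
bolusmap simulate --out phantom.nii --noise-sd 0.05 --seed 7
bolusmap run --out run1 --seed 7
bolusmap compare run1 run2 --kind toa_norm
```

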
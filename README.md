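# plsbeam

PLS-aided minimum-variance beamforming for MEG source localization, with a
built-in dipole simulator and evaluation harness.

## The problem

Magnetoencephalography (MEG) records the magnetic field of neuronal currents
at a few hundred sensors; locating the underlying source — e.g. the generator
of an epileptiform spike — is an ill-posed inverse problem. The linearly
constrained minimum-variance (LCMV) beamformer scans a grid of candidate
locations with a spatial filter

```
W'(r) = [L'(r) C⁻¹ L(r)]⁻¹ L'(r) C⁻¹
```

that passes activity at `r` with unit gain (`W'L = I`) while minimizing the
total output power `tr(W'CW)`. The output-power ("variance") map

```
Var(r) = tr{ [L'(r) C⁻¹ L(r)]⁻¹ }
```

peaks at the estimated source. Here `L(r)` is the M×3 lead-field gain matrix
and `C` the M×M sensor covariance. Because `C` is estimated from noisy data,
the scan is noise-sensitive.

The PLS-aided variant (**pLCMV**) denoises the sensor matrix first. Each
channel is a sample of an M×N data block `X`, labelled by its brain region
through an M×8 one-hot class matrix `Y` (frontal / temporal / parietal /
occipital, left and right). Two-block partial least squares extracts weight
pairs

```
w_k = argmax_{||w||=||v||=1} Cov²(Xw, Yv)     s.t. uncorrelated scores t_k
```

and `X` is reconstructed from the first K score/loading pairs,
`X̂ = T P'` (de-standardized). The beamformer then scans with `C(X̂)` —
inverted with relative diagonal loading, since the reconstruction is
rank-deficient.

The package is aimed at methods researchers in electrophysiological source
imaging: everything runs on synthetic data from its own simulator (sinc-
waveform current dipole in a conducting sphere, 306-channel helmet geometry,
calibrated Gaussian noise ladder), so no recordings are required.

## Worked example

```python
import numpy as np
from plsbeam import (ExperimentConfig, NoiseSpec, SourceSpec, add_noise,
                     lcmv_localize, pls_lcmv_localize, project_dipole)
from plsbeam.harness import build_context

ctx = build_context(ExperimentConfig())        # helmet, partition, grid, lead field
loc = ctx.grid.points[ctx.grid.nearest(np.array([-29.0, 11.0, 38.0]))[0]]
tang = np.cross(loc - ctx.sphere.center, [0.0, 0.0, 1.0])
tang /= np.linalg.norm(tang)
clean, _, _ = project_dipole(SourceSpec(location=loc, orientation=tang), ctx.lead)
ds = add_noise(clean, NoiseSpec(sigma=float(np.sqrt((clean**2).mean())), seed=2))

res = pls_lcmv_localize(ds.observed, ctx.partition, ctx.lead)
print(ds.snr_db, res.location, res.K_used)
```

Running `examples/04_localize.py` (the same computation) prints:

```
true source: [-30.  10.  40.] mm, observed SNR 0.01 dB
LCMV   peak at [-30.0, 10.0, 40.0] mm, location error 0.0 mm
pLCMV  peak at [-30.0, 10.0, 40.0] mm, location error 0.0 mm, K = 30
```

The requested source snaps to the nearest grid point (−30, 10, 40); at ~0 dB
SNR both scans still place the variance-map maximum on the exact source
point, so the location error (Euclidean distance between true and estimated
position) is 0 mm. `K = 30` is the number of PLS components kept in the
reconstruction. The other scripts in `examples/` walk through geometry
construction, simulation, denoising and the sweep experiment one capability
at a time.

A thin CLI wraps the same functions:

```bash
plsbeam simulate --source 35 11 38 --sigma 2.0 --seed 1 --out data/
plsbeam localize --data data/observed.csv --layout data/layout.csv \
    --grid data/grid.csv --method plcmv --out result.json
plsbeam sweep --out results/ --reps 5
plsbeam report results/
```

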
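# Methods

## Scope and model

`plsbeam` implements a region-supervised PLS denoising step in front of an
LCMV beamformer scan, together with the synthetic data machinery needed to
evaluate it: helmet geometry, an analytic forward model, a dipole simulator
with a calibrated noise ladder, and a sweep harness. Everything is
deterministic given its inputs; all randomness flows through explicit seeds.

Units are fixed throughout: positions in mm (head frame: x right, y anterior,
z superior), dipole moments in nAm, magnetometer signals in fT, planar-
gradiometer signals in fT/mm. Unit conversions happen only at I/O boundaries.

## Sensor array and region partition

The helmet emulates a 306-channel whole-head system: 102 triplet sites (one
magnetometer + two orthogonal planar gradiometers each) on a spherical cap of
radius `sphere.radius + 20 mm`, restricted to elevations above −30°, laid out
by a deterministic Fibonacci lattice. Real instrument coordinates are
proprietary, so the layout is synthetic but matches the qualitative geometry
(quasi-uniform coverage, triplets, helmet shape).

Sensors are partitioned into eight lobes by site geometry: hemisphere from
the sign of x (ties to the left), lobe from the sagittal-plane angle
ψ = atan2(z, y) relative to the sphere center with cut angles −10°, 55° and
125° separating temporal / frontal / parietal / occipital sectors (|ψ| ≥ 125°
is occipital; boundary angles go to the more anterior lobe). The cuts were
chosen once so that all eight regions are populated and reasonably balanced
on the default 102-site helmet (24–54 channels per region); they are
arguments of `partition_regions` for other layouts. Mirroring the array
through the mid-sagittal plane provably swaps L/R labels and preserves lobes.

## Forward model

The volume conductor is a homogeneous conducting sphere (default: center
(0, 0, 40) mm, radius 75 mm — a typical adult head). The magnetic field of a
current dipole in a sphere has a closed-form solution including volume
currents; the package evaluates its projection on each coil normal through
per-sensor sensitivity ("lead") vectors, so the field is exactly linear in
the dipole moment. Two consequences of spherical symmetry are used as test
oracles: radially oriented dipoles are silent, and a dipole at the center is
silent.

Planar gradiometers are modeled as two-point finite differences of the
normal-component field along a tangential baseline (default 17 mm),
capturing their spatial high-pass character without coil-integration
machinery. Magnetometers return the plain field.

The scan grid is an axis-aligned lattice (default 10 mm spacing) clipped to
`||p − c|| ≤ radius − 10 mm`. The experiment harness additionally excludes a
25 mm core around the sphere center (`central_exclusion`): a spherical
conductor is magnetically near-silent there, gains fall by another factor of
~3 between 28 mm depth and the center region, and under sensor noise the
unnormalized variance map otherwise always peaks at the weakest-gain point
(the textbook depth bias; volume source spaces built on sphere models
conventionally exclude a comparable core). The geometry-level default for
`central_exclusion` is 0 so that grid construction follows the plain
clipping rule.

## PLS extraction and reconstruction

Channels are samples: `X` is M×N (M channels, N = 600 time points), `Y` is
the M×8 one-hot region indicator. Both blocks are column-standardized (each
time-point column of `X`, each indicator column of `Y`, to mean 0 /
variance 1); a constant column is an error. Extraction is the classical
two-block iterative scheme with both-block deflation:

1. `(w_k, v_k)` = leading singular pair of `X'Y` on the current deflated
   blocks, found by power iteration on the 8×8 Gram matrix `(X'Y)'(X'Y)`
   (cap 500 iterations, tolerance 1e−10 on the weight change). When the two
   leading singular values nearly tie — routine once the `Y` block is nearly
   exhausted — the iteration cannot settle within the cap and the pair is
   finished with an exact thin SVD of the same N×8 matrix (deterministic,
   identical fixed point).
2. `t_k = X w_k`, loading `p_k = X't_k / (t_k't_k)`, response loading
   `c_k = Y't_k / (t_k't_k)`; deflate `X ← X − t p'` and (by default)
   `Y ← Y − t c'`.
3. Stop when the spectral norm of the deflated `X` falls below
   `0.05 · ||X||₂` or after `K ≤ min(M, N, 30)` components. Residual
   spectral norms are tracked per step (power iteration with warm start,
   tolerance 1e−6 — the stopping rule only needs ~3 significant digits);
   deflation is an orthogonal projection, so they are non-increasing by
   construction.

If `||X'Y||` is numerically zero (the supervision fully consumed), further
components follow the leading principal direction of the deflated `X`, with
`v_k = 0`. This lets `K` reach `rank(X)` so that the full-rank
reconstruction is exact — the property behind the pLCMV→LCMV degeneracy
test. Weight signs are fixed (largest-magnitude entry positive) to remove
the SVD sign ambiguity.

The reconstruction `X̂ = T P'` is de-standardized back to physical units
before any covariance is formed: per-time-point z-scores have no physical
field scale, and the beamformer needs covariances of measured signals.

## Beamformer

`C = (X − rowmeans)(X − rowmeans)' / (N − 1)` (unbiased; the map argmax is
invariant to the 1/N vs 1/(N−1) choice). Inversion uses relative diagonal
loading, `inv(C + λ (tr C / M) I)` with λ = 1e−4 by default for both LCMV
and pLCMV — mandatory for pLCMV because `rank(C(X̂)) ≤ K ≪ M`; a plain
inverse (λ = 0) errors on singular input with a hint to enable loading.

In a spherical conductor the radial column of every `L(r)` is exactly
silent, so the 3×3 matrix `L'C⁻¹L` has rank 2 at every grid point. The
variance map therefore takes `tr{[L'C⁻¹L]⁻¹}` over the eigenvalues above
`1e−8 ×` the largest — the matrix analogue of the standard rank-2 lead-field
reduction for MEG — and marks points with fewer than two usable directions
(e.g. the exact center) as degenerate/NaN, excluded from the argmax. Ties in
the argmax break to the lowest grid index.

## Simulation conditions

The source waveform is `s(t) = sin(π(t+τ))/(π(t+τ))` on a centered time
axis: 600 samples at 1000 Hz, scaled so the main lobe spans ~100 ms of the
600 ms window (`time_scale = 20` sinc units per second), shift τ = 0 by
default. The removable singularity evaluates to exactly 1. The default
dipole is tangential (maximally visible to MEG) with amplitude 100 nAm — a
typical equivalent-dipole strength for epileptiform transients; the
amplitude cancels out of every SNR-calibrated experiment.

Sensor noise is i.i.d. Gaussian per channel-sample. The 12-level ladder uses
a geometric sigma grid calibrated analytically from the clean matrix via
`E||B||²_F = σ²MN` so that the expected SNR
(`10 log₁₀(||A||²_F / ||B||²_F)`) runs from 6.990 dB at level 1 to 0.043 dB
at level 12. Each repetition draws one noise realization and reuses it
(scaled) across levels, so SNR decreases with level for every seed, not just
in mean. Default: 50 repetitions per level. Simulated dipoles sit exactly on
grid points by default (off-grid placement up to one grid spacing is
supported); the localization task is then exact recovery of a known index.

## Sweep experiments and comparison

The harness builds geometry and lead field once and, for each source ×
level × repetition cell, localizes the same noisy dataset with every
configured method (paired design — statistically stronger than independent
noise per method, and flagged in the output metadata). The six benchmark
locations (−29, 11, 38), (67, 11, 30), (59, 43, 70), (59, −53, 54),
(67, −29, 86), (35, 11, 38) mm are snapped to the nearest grid point (snap
distance logged; sources 1 and 6 tagged deep). The every-12th-grid-point
experiment reuses the same machinery over `subsample_grid` indices.

`compare_methods` reports per-level means, paired pLCMV−LCMV differences
with bootstrap 95% intervals (resampling cells within level), and one-sided
Kendall trend tests of error against noise level. The monotonicity check is
one-sided in the conservative direction: errors must not *significantly
decrease* as noise grows (an all-tied, e.g. all-zero, error sequence is flat
and passes); the complementary p-value for an increasing trend is reported
alongside.

## What the desk-scale results show — and what they do not

The sphere, helmet and grid are a synthetic stand-in for a subject's
MRI-derived head model, and the scan uses the same forward model that
generated the data. That matched setting makes the desk-scale problem easy:
with 600 samples and SNR ≥ 0 dB both LCMV and pLCMV localize grid-point
sources exactly at most noise levels, so the method comparison is carried by
the few noisiest levels and absolute error magnitudes are not comparable to
experiments with realistic head models, model mismatch, or physiological
noise. The simulator deliberately omits correlated sensor noise, cardiac and
ocular artifacts, and realistic spike morphology; passing sweeps therefore
validate the pipeline's correctness and internal orderings, not clinical
performance.

Two structural properties of pLCMV visible at desk scale are worth noting.
First, with `K_use = rank(X)` it reproduces LCMV exactly (a standing
regression test). Second, at the lowest SNRs the rank-30 reconstruction
misses a noise-limited sliver (~0.2% in energy) of the true source pattern,
and the loaded inverse amplifies that residual in the reconstruction's null
space, occasionally displacing the map peak — so its worst-level error can
exceed LCMV's here even though the reconstruction itself is closer to the
clean signal. This is a genuine property of low-rank covariances under the
unnormalized variance map in a matched-model regime, not a numerical
artifact.

## Numerical choices and limitations

- Loading λ = 1e−4 (relative) everywhere; config-exposed. Nothing forces a
  single "right" value: larger loading damps noise sensitivity but biases
  the map, and the reports flag the value used.
- Degenerate scan points are skipped, not fatal; a fully degenerate map is.
- The class matrix errors on a region emptied by channel masking
  (`drop_empty=True` relaxes this, e.g. for single-region studies).
- Multiple-comparison correction is deliberately absent from the per-level
  bootstrap intervals; they are descriptive.
- Single-source scans only: the argmax localizes one source. Multi-source
  extensions (e.g. thresholded map peaks) are out of scope.
- Sweep problem sizes default to 6 sources × 12 levels × 50 repetitions on a
  ~1,100-point grid — the package's standard desk-scale experiment; larger
  grids or rep counts scale linearly through the same configs.
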
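"""Ground-truth dipole simulations: sinc waveform, sensor projection, noise ladder.

The simulated source is a current dipole with a sinc time course,
s(t) = sin(pi(t + tau)) / (pi(t + tau)), the classic stand-in for an
epileptiform transient.  Defaults follow the study conditions emulated by the
package: 600 samples at 1000 Hz (600 ms), a 12-level additive Gaussian noise
ladder calibrated so the mean SNR falls from about 7 dB to about 0 dB, and 50
noise realizations per level.  SNR is the decibel ratio of squared Frobenius
norms of the clean and noise matrices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .forward import LeadField
from .geometry import HeadSphere

__all__ = [
    "SourceSpec",
    "NoiseSpec",
    "SimDataset",
    "sinc_waveform",
    "project_dipole",
    "add_noise",
    "noise_ladder",
    "calibrate_sigma_ladder",
    "snr_db",
    "DEFAULT_FS",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_TIME_SCALE",
    "SNR_TOP_DB",
    "SNR_BOTTOM_DB",
]

DEFAULT_FS = 1000.0          # Hz
DEFAULT_N_SAMPLES = 600      # 600 ms at 1 kHz
DEFAULT_TIME_SCALE = 20.0    # sinc units per second: main lobe spans ~100 ms
SNR_TOP_DB = 6.990           # ladder calibration endpoints (mean SNR, dB)
SNR_BOTTOM_DB = 0.043
DEFAULT_N_LEVELS = 12
DEFAULT_N_REPS = 50


@dataclass
class SourceSpec:
    """A single simulated current dipole and its moment time course."""

    location: np.ndarray                 # (3,) mm
    orientation: np.ndarray              # (3,) unit vector
    amplitude: float = 100.0             # nAm, typical epileptiform transient
    waveform: np.ndarray | None = None   # (N,) unitless moment time course
    tau: float = 0.0                     # sinc shift, seconds
    fs: float = DEFAULT_FS
    n_samples: int = DEFAULT_N_SAMPLES
    time_scale: float = DEFAULT_TIME_SCALE

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("orientation must be a unit vector")
        if self.waveform is None:
            self.waveform = sinc_waveform(self.n_samples, self.fs,
                                          tau=self.tau * self.time_scale,
                                          time_scale=self.time_scale)
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.n_samples = self.waveform.size

    def validate_inside(self, sphere: HeadSphere) -> None:
        if np.linalg.norm(self.location - sphere.center) >= sphere.radius:
            raise ValueError("source location must be inside the head sphere")


@dataclass
class NoiseSpec:
    """One rung of the noise ladder: per-entry Gaussian sd and its seed."""

    sigma: float                 # field-noise sd per channel-sample (fT)
    seed: int | np.random.SeedSequence = 0
    level: int | None = None     # 1-based ladder level, if part of a ladder

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("noise sigma must be positive")


@dataclass
class SimDataset:
    """Clean + noise decomposition of one simulated recording."""

    clean: np.ndarray            # A, (M, N) fT
    noise: np.ndarray            # B, (M, N) fT
    truth: SourceSpec | None = None
    fs: float = DEFAULT_FS
    level: int | None = None
    seed: int | None = None
    snr_db: float = field(init=False)

    def __post_init__(self):
        self.snr_db = snr_db(self.clean, self.noise)

    @property
    def observed(self) -> np.ndarray:
        return self.clean + self.noise

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.clean.shape[1] / self.fs

    def manifest(self) -> dict:
        d = {"snr_db": self.snr_db, "fs": self.fs, "level": self.level,
             "seed": self.seed, "duration_ms": self.duration_ms}
        if self.truth is not None:
            d.update(location=self.truth.location.tolist(),
                     orientation=self.truth.orientation.tolist(),
                     amplitude=self.truth.amplitude)
        return d

    def save(self, directory) -> None:
        import pathlib
        p = pathlib.Path(directory)
        p.mkdir(parents=True, exist_ok=True)
        np.savetxt(p / "observed.csv", self.observed, delimiter=",")
        np.savetxt(p / "clean.csv", self.clean, delimiter=",")
        np.savetxt(p / "noise.csv", self.noise, delimiter=",")
        (p / "truth.json").write_text(json.dumps(self.manifest(), indent=2))


def snr_db(A: np.ndarray, B: np.ndarray) -> float:
    """10 log10(||A||_F^2 / ||B||_F^2): clean-signal to noise power ratio in dB."""
    return 10.0 * math.log10(np.sum(A * A) / np.sum(B * B))


def sinc_waveform(n_samples: int = DEFAULT_N_SAMPLES, fs: float = DEFAULT_FS,
                  tau: float = 0.0,
                  time_scale: float = DEFAULT_TIME_SCALE) -> np.ndarray:
    """Sampled s(t) = sin(pi(t + tau)) / (pi(t + tau)) on a centered time axis.

    The axis is t_i = (i - n/2) / fs * time_scale, so ``tau`` is in the same
    scaled (dimensionless sinc) units; the removable singularity at
    t + tau = 0 evaluates to exactly 1.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = (np.arange(n_samples) - n_samples // 2) / fs * time_scale
    return np.sinc(t + tau)


def project_dipole(spec: SourceSpec, lead: LeadField,
                   snap: bool = True) -> tuple[np.ndarray, int, float]:
    """Rank-1 clean sensor matrix A = L(gamma) m s' for the dipole ``spec``.

    Returns (A, grid_index, snap_distance_mm).  With ``snap`` the dipole is
    placed on the nearest grid point (the grid-point experiments' default);
    a location farther than one grid spacing from any point is rejected.
    """
    idx, dist = lead.grid.nearest(spec.location)
    if dist > lead.grid.spacing * (1.0 if snap else 0.5) + 1e-9:
        raise ValueError(
            f"source location {spec.location} is {dist:.1f} mm from the nearest "
            "grid point; outside the grid hull"
        )
    moment = spec.amplitude * spec.orientation
    gain = lead.gains[idx] @ moment                  # (M,) fT per unit waveform
    A = np.outer(gain, spec.waveform)
    return A, idx, dist


def add_noise(clean: np.ndarray, noise_spec: NoiseSpec,
              truth: SourceSpec | None = None, fs: float = DEFAULT_FS) -> SimDataset:
    """Add i.i.d. Gaussian N(0, sigma^2) noise to the clean matrix, seeded."""
    rng = np.random.default_rng(noise_spec.seed)
    B = noise_spec.sigma * rng.standard_normal(clean.shape)
    seed = noise_spec.seed if isinstance(noise_spec.seed, (int, np.integer)) else None
    return SimDataset(clean=np.asarray(clean, dtype=float), noise=B, truth=truth,
                      fs=fs, level=noise_spec.level, seed=seed)


def calibrate_sigma_ladder(clean: np.ndarray, n_levels: int = DEFAULT_N_LEVELS,
                           snr_top_db: float = SNR_TOP_DB,
                           snr_bottom_db: float = SNR_BOTTOM_DB) -> np.ndarray:
    """Geometric sigma grid whose expected SNR spans [snr_top, snr_bottom] dB.

    Uses E||B||_F^2 = sigma^2 M N, so sigma_1 solves the top-level SNR and the
    ratio g spreads the remaining levels evenly in dB.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 noise levels")
    clean_power = float(np.sum(clean * clean))
    if clean_power == 0:
        raise ValueError("clean matrix is identically zero; cannot set an SNR")
    mn = clean.size
    sigma1 = math.sqrt(clean_power / mn) * 10.0 ** (-snr_top_db / 20.0)
    g = 10.0 ** ((snr_top_db - snr_bottom_db) / (20.0 * (n_levels - 1)))
    return sigma1 * g ** np.arange(n_levels)


def noise_ladder(clean: np.ndarray, n_levels: int = DEFAULT_N_LEVELS,
                 n_reps: int = DEFAULT_N_REPS, base_seed: int = 0,
                 truth: SourceSpec | None = None,
                 snr_top_db: float = SNR_TOP_DB,
                 snr_bottom_db: float = SNR_BOTTOM_DB,
                 ) -> tuple[list[list[SimDataset]], np.ndarray]:
    """Full noise ladder: ``datasets[level][rep]`` plus per-level mean SNR.

    Each (level, rep) cell draws from an independent, reproducible stream
    spawned from ``base_seed``; sigma is monotone increasing with level, so
    SNR decreases with level for every shared seed, not just on average.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sigmas = calibrate_sigma_ladder(clean, n_levels, snr_top_db, snr_bottom_db)
    datasets: list[list[SimDataset]] = []
    for lvl in range(n_levels):
        row = []
        for rep in range(n_reps):
            # one noise realization per rep, shared across levels up to the
            # sigma scale, so SNR is monotone in level for every single seed
            ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(rep,))
            spec = NoiseSpec(sigma=float(sigmas[lvl]), seed=ss, level=lvl + 1)
            row.append(add_noise(clean, spec, truth=truth))
        datasets.append(row)
    mean_snr = np.array([np.mean([d.snr_db for d in row]) for row in datasets])
    return datasets, mean_snr
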
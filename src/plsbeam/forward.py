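"""Analytic single-sphere MEG forward model.

A current dipole inside a homogeneous conducting sphere produces an external
magnetic field with a closed-form expression (volume currents included); the
radial projection depends only on the primary current, and radially oriented
dipoles are magnetically silent.  Channels are either magnetometers (field
along the coil normal) or planar gradiometers (two-point finite difference of
that field component along a tangential baseline).

Units are fixed package-wide: positions in mm, dipole moments in nAm, fields
in fT (gradiometers: fT/mm).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import HeadSphere, SensorArray, SourceGrid, channel_type_mask

__all__ = [
    "LeadField",
    "sphere_dipole_field",
    "gradiometer_response",
    "compute_leadfield",
    "save_leadfield",
    "load_leadfield",
    "export_gain_norms_csv",
]

# mu0/(4*pi) in T*m/A; with positions in mm (1e-3 m), moments in nAm (1e-9 A*m)
# and output in fT (1e15), the combined prefactor is
#   1e-7 * 1e-9 / (1e-3)^2 * 1e15 = 1e5   [fT per (nAm / mm^2)]
_PREFACTOR = 1e5


@dataclass
class LeadField:
    """Per-grid-point gain matrices linking dipole moments to channel signals.

    ``gains[p, m, j]`` is the signal on channel ``m`` produced by a unit
    (1 nAm) dipole along axis ``j`` at grid point ``p``.
    """

    gains: np.ndarray            # (P, M_sel, 3)
    grid: SourceGrid
    channel_index: np.ndarray    # (M_sel,) indices into the full array

    @property
    def n_points(self) -> int:
        return self.gains.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[1]

    @property
    def n_dipole_params(self) -> int:
        return 3 * self.n_points


def _lead_vectors(dipole_pos: np.ndarray, obs_pos: np.ndarray,
                  obs_normal: np.ndarray, sphere: HeadSphere) -> np.ndarray:
    """Sensitivity vectors l such that B_normal = l . moment, vectorized over
    observation points.

    Implements the conducting-sphere solution in the form
    ``B(r) = k/F^2 * (F (Q x r0) - ((Q x r0) . r) grad F)`` with the dipole at
    ``r0`` and observation at ``r`` (both relative to the sphere center).
    Projecting on the coil normal ``n`` and using the triple-product identity
    gives ``B . n = (r0 x g) . Q`` with ``g = k/F^2 (F n - (grad F . n) r)``.
    """
    c = sphere.center
    r0 = np.asarray(dipole_pos, dtype=float) - c        # (3,)
    r = np.atleast_2d(obs_pos) - c                      # (K, 3)
    n = np.atleast_2d(obs_normal)                       # (K, 3)
    a_vec = r - r0                                      # (K, 3)
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("kj,kj->k", a_vec, r)
    F = a * (R * a + R**2 - r0_dot_r)
    gradF = ((a**2 / R + a_dot_r / a + 2.0 * a + 2.0 * R)[:, None] * r
             - (a + 2.0 * R + a_dot_r / a)[:, None] * r0)
    g = (_PREFACTOR / F**2)[:, None] * (F[:, None] * n
                                        - np.einsum("kj,kj->k", gradF, n)[:, None] * r)
    return np.cross(np.broadcast_to(r0, g.shape), g)    # (K, 3)


def sphere_dipole_field(dipole_pos, moment, sphere: HeadSphere,
                        obs_pos, obs_normal) -> float:
    """Magnetic field component (fT) along ``obs_normal`` at ``obs_pos``.

    The dipole must be strictly inside the sphere and the observation point
    strictly outside.  A dipole at the center, or one oriented radially, gives
    exactly zero (silent sources of the spherical conductor).
    """
    dipole_pos = np.asarray(dipole_pos, dtype=float)
    obs_pos = np.asarray(obs_pos, dtype=float)
    if np.linalg.norm(dipole_pos - sphere.center) >= sphere.radius:
        raise ValueError("dipole must be strictly inside the head sphere")
    if np.linalg.norm(obs_pos - sphere.center) <= sphere.radius:
        raise ValueError("observation point must be strictly outside the head sphere")
    lead = _lead_vectors(dipole_pos, obs_pos[None, :], np.asarray(obs_normal, float)[None, :],
                         sphere)
    return float(lead[0] @ np.asarray(moment, dtype=float))


def _channel_lead(dipole_pos, sphere: HeadSphere, array: SensorArray,
                  idx: np.ndarray) -> np.ndarray:
    """Lead vectors (K, 3) for the channels ``idx`` of ``array``."""
    pos = array.channel_positions[idx]
    nrm = array.channel_orientations[idx]
    types = array.channel_types[idx]
    is_grad = types != "magnetometer"
    out = np.zeros((idx.size, 3))
    if np.any(~is_grad):
        out[~is_grad] = _lead_vectors(dipole_pos, pos[~is_grad], nrm[~is_grad], sphere)
    if np.any(is_grad):
        b = array.baseline_mm[idx][is_grad][:, None]
        if np.any(~np.isfinite(b)) or np.any(b == 0):
            raise ValueError("gradiometer with zero or undefined baseline")
        d = array.baseline_dir[idx][is_grad]
        lp = _lead_vectors(dipole_pos, pos[is_grad] + 0.5 * b * d, nrm[is_grad], sphere)
        lm = _lead_vectors(dipole_pos, pos[is_grad] - 0.5 * b * d, nrm[is_grad], sphere)
        out[is_grad] = (lp - lm) / b
    return out


def gradiometer_response(dipole_pos, moment, sphere: HeadSphere,
                         array: SensorArray, channel: int) -> float:
    """Signal of one channel: field for magnetometers (fT), finite-difference
    planar gradient along the baseline for gradiometers (fT/mm)."""
    lead = _channel_lead(np.asarray(dipole_pos, float), sphere, array,
                         np.array([channel]))
    return float(lead[0] @ np.asarray(moment, dtype=float))


def compute_leadfield(grid: SourceGrid, array: SensorArray, sphere: HeadSphere,
                      channel_mask=None) -> LeadField:
    """Assemble the (P, M_sel, 3) gain tensor over the scan grid.

    ``channel_mask`` may be a boolean mask, an index array, or one of the
    selector strings 'grads' / 'mags' / 'all'.
    """
    if channel_mask is None:
        channel_mask = "all"
    if isinstance(channel_mask, str):
        channel_mask = channel_type_mask(array, channel_mask)
    channel_mask = np.asarray(channel_mask)
    idx = (np.flatnonzero(channel_mask) if channel_mask.dtype == bool
           else channel_mask.astype(int))
    if idx.size == 0:
        raise ValueError("empty channel selection")
    gains = np.empty((grid.n_points, idx.size, 3))
    for p, pos in enumerate(grid.points):
        gains[p] = _channel_lead(pos, sphere, array, idx)
    return LeadField(gains=gains, grid=grid, channel_index=idx)


def save_leadfield(path, lead: LeadField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gains", data=lead.gains, compression="gzip")
        f.create_dataset("grid_points", data=lead.grid.points)
        f.attrs["grid_spacing"] = lead.grid.spacing
        f.create_dataset("channel_index", data=lead.channel_index)


def load_leadfield(path) -> LeadField:
    with h5py.File(path, "r") as f:
        grid = SourceGrid(points=f["grid_points"][()],
                          spacing=float(f.attrs["grid_spacing"]))
        return LeadField(gains=f["gains"][()], grid=grid,
                         channel_index=f["channel_index"][()])


def export_gain_norms_csv(path, lead: LeadField) -> None:
    """Frobenius norm of each grid point's gain matrix, for quick inspection."""
    norms = np.linalg.norm(lead.gains, axis=(1, 2))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "x", "y", "z", "gain_frobenius"])
        for i, (p, v) in enumerate(zip(lead.grid.points, norms)):
            w.writerow([i, *p, v])
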
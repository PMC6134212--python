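"""Synthetic MEG helmet geometry: sensor array, region partition, head sphere, source grid.

The sensor layout emulates a 306-channel whole-head system: 102 sites on a
helmet-shaped cap, each carrying one magnetometer and two orthogonal planar
gradiometers.  Coordinates follow the Neuromag head frame (x toward the right
ear, y toward the nasion, z superior, all in mm).  Because the real
instrument's channel coordinates are proprietary, sites are laid out on a
deterministic Fibonacci lattice over a spherical cap and partitioned into the
eight classical lobes (frontal / temporal / parietal / occipital, left and
right) by simple geometric rules.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeadSphere",
    "SensorArray",
    "RegionPartition",
    "SourceGrid",
    "REGION_ORDER",
    "CHANNEL_TYPES",
    "build_helmet_array",
    "partition_regions",
    "build_source_grid",
    "subsample_grid",
    "channel_type_mask",
    "save_layout_csv",
    "load_layout_csv",
    "save_grid_csv",
    "load_grid_csv",
]

#: Fixed ordering of the eight sensor regions (columns of the class matrix).
REGION_ORDER = (
    "frontal-L",
    "frontal-R",
    "temporal-L",
    "temporal-R",
    "parietal-L",
    "parietal-R",
    "occipital-L",
    "occipital-R",
)

CHANNEL_TYPES = ("magnetometer", "planar_grad_1", "planar_grad_2")

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class HeadSphere:
    """Spherical volume-conductor model of the head.

    Parameters are in mm in Neuromag-style head coordinates.  The default
    (center 40 mm above the origin, radius 75 mm) is a typical adult head.
    """

    center: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 40.0]))
    radius: float = 75.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("sphere center must be a 3-vector")
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where ``||p - center|| <= radius - margin`` (row-wise)."""
        d = np.linalg.norm(np.atleast_2d(points) - self.center, axis=1)
        return d <= self.radius - margin


@dataclass
class SensorArray:
    """Helmet sensor array: M channels grouped in triplet sites.

    ``channel_orientations`` is the coil normal (radial) for every channel;
    planar gradiometers additionally carry a tangential ``baseline_dir`` and
    ``baseline_mm`` describing the two-coil finite-difference axis.
    Magnetometer rows of ``baseline_dir`` are zero and their baseline is NaN.
    """

    site_positions: np.ndarray          # (S, 3) mm
    channel_positions: np.ndarray       # (M, 3) mm
    channel_orientations: np.ndarray    # (M, 3) unit coil normals
    channel_types: np.ndarray           # (M,) str in CHANNEL_TYPES
    site_index: np.ndarray              # (M,) site of each channel
    baseline_dir: np.ndarray            # (M, 3) unit tangential dirs (grads)
    baseline_mm: np.ndarray             # (M,) baseline length, NaN for mags

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channel_positions.shape[0]

    def validate(self, sphere: HeadSphere | None = None) -> None:
        M = self.n_channels
        if not (self.channel_orientations.shape == (M, 3)
                and self.channel_types.shape == (M,)
                and self.site_index.shape == (M,)):
            raise ValueError("inconsistent channel array shapes")
        norms = np.linalg.norm(self.channel_orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ValueError("channel orientations must be unit vectors")
        if sphere is not None:
            d = np.linalg.norm(self.channel_positions - sphere.center, axis=1)
            if np.any(d <= sphere.radius):
                raise ValueError("all channels must lie strictly outside the head sphere")


@dataclass
class RegionPartition:
    """Assignment of every channel to exactly one of the eight lobes."""

    labels: np.ndarray                      # (M,) str, entries of region_order
    region_order: tuple = REGION_ORDER

    @property
    def counts(self) -> dict:
        return {r: int(np.sum(self.labels == r)) for r in self.region_order}

    @property
    def n_regions(self) -> int:
        return len(self.region_order)

    def validate(self) -> None:
        known = set(self.region_order)
        if not set(np.unique(self.labels)) <= known:
            raise ValueError("unknown region label present")
        if sum(self.counts.values()) != self.labels.shape[0]:
            raise AssertionError("region counts must sum to the channel count")


@dataclass
class SourceGrid:
    """Regular scan lattice of candidate source locations inside the head."""

    points: np.ndarray      # (P, 3) mm, lexicographic in (x, y, z)
    spacing: float          # mm

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def nearest(self, location) -> tuple[int, float]:
        """Index of the grid point nearest to ``location`` and the snap distance."""
        d = np.linalg.norm(self.points - np.asarray(location, dtype=float), axis=1)
        i = int(np.argmin(d))
        return i, float(d[i])


def _tangent_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic orthonormal tangent pair for a radial coil normal.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(normal @ ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    d1 = ref - (ref @ normal) * normal
    d1 /= np.linalg.norm(d1)
    d2 = np.cross(normal, d1)
    return d1, d2


def build_helmet_array(
    n_sites: int = 102,
    sphere: HeadSphere | None = None,
    shell_offset: float = 20.0,
    elevation_cutoff_deg: float = -30.0,
    gradiometer_baseline_mm: float = 17.0,
) -> SensorArray:
    """Lay out ``n_sites`` triplet sites on a helmet cap around the head sphere.

    Sites sit on a sphere of radius ``sphere.radius + shell_offset`` (same
    center), quasi-uniformly by a Fibonacci lattice restricted to elevations
    above ``elevation_cutoff_deg``.  Each site emits one magnetometer plus two
    orthogonal planar gradiometers, so M = 3 * n_sites.  Deterministic.
    """
    sphere = sphere or HeadSphere()
    if n_sites < 8:
        raise ValueError("need at least 8 sites to cover the eight regions")
    if not shell_offset > 0:
        raise ValueError("shell_offset must be positive")

    rho = sphere.radius + shell_offset
    u_min = math.sin(math.radians(elevation_cutoff_deg))
    # Fibonacci cap: descend from the vertex, golden-angle azimuths.
    i = np.arange(n_sites)
    u = 1.0 - (1.0 - u_min) * (i + 0.5) / n_sites      # sin(elevation)
    az = i * _GOLDEN_ANGLE
    r_xy = np.sqrt(1.0 - u**2)
    unit = np.column_stack([r_xy * np.cos(az), r_xy * np.sin(az), u])
    sites = sphere.center + rho * unit

    M = 3 * n_sites
    positions = np.repeat(sites, 3, axis=0)
    normals = np.repeat(unit, 3, axis=0)
    types = np.tile(np.array(CHANNEL_TYPES, dtype=object), n_sites)
    site_index = np.repeat(i, 3)
    baseline_dir = np.zeros((M, 3))
    baseline = np.full(M, np.nan)
    for s in range(n_sites):
        d1, d2 = _tangent_frame(unit[s])
        baseline_dir[3 * s + 1] = d1
        baseline_dir[3 * s + 2] = d2
        baseline[3 * s + 1] = gradiometer_baseline_mm
        baseline[3 * s + 2] = gradiometer_baseline_mm

    array = SensorArray(
        site_positions=sites,
        channel_positions=positions,
        channel_orientations=normals,
        channel_types=types,
        site_index=site_index,
        baseline_dir=baseline_dir,
        baseline_mm=baseline,
    )
    array.validate(sphere)
    return array


def _site_labels(
    rel: np.ndarray,
    frontal_temporal_cut: float,
    frontal_parietal_cut: float,
    parietal_occipital_cut: float,
) -> np.ndarray:
    """Lobe+hemisphere label per site position (relative to sphere center).

    Hemisphere is the sign of x (ties -> left).  The lobe is decided by the
    sagittal-plane angle psi = atan2(z, y) in degrees: frontal for
    [ft_cut, fp_cut), parietal for [fp_cut, po_cut), occipital for
    |psi| >= po_cut, temporal for [-po_cut, ft_cut).  Boundary angles are
    assigned to the more anterior lobe.
    """
    psi = np.degrees(np.arctan2(rel[:, 2], rel[:, 1]))
    lobe = np.empty(rel.shape[0], dtype=object)
    lobe[:] = "temporal"
    lobe[(psi >= frontal_temporal_cut) & (psi < frontal_parietal_cut)] = "frontal"
    lobe[(psi >= frontal_parietal_cut) & (psi < parietal_occipital_cut)] = "parietal"
    lobe[np.abs(psi) >= parietal_occipital_cut] = "occipital"
    hemi = np.where(rel[:, 0] > 0, "R", "L")
    return np.array([f"{l}-{h}" for l, h in zip(lobe, hemi)], dtype=object)


def partition_regions(
    array: SensorArray,
    sphere: HeadSphere | None = None,
    frontal_temporal_cut: float = -10.0,
    frontal_parietal_cut: float = 55.0,
    parietal_occipital_cut: float = 125.0,
) -> RegionPartition:
    """Label every channel with one of the eight lobes by site geometry.

    All three channels of a site share the label.  Raises if any region is
    empty (a degenerate class matrix would follow).
    """
    sphere = sphere or HeadSphere()
    if array.n_channels == 0:
        raise ValueError("empty sensor array")
    rel = array.site_positions - sphere.center
    site_lab = _site_labels(
        rel, frontal_temporal_cut, frontal_parietal_cut, parietal_occipital_cut
    )
    labels = site_lab[array.site_index]
    part = RegionPartition(labels=labels)
    empty = [r for r, n in part.counts.items() if n == 0]
    if empty:
        raise ValueError(f"empty region(s) for this array: {empty}")
    part.validate()
    return part


def build_source_grid(
    sphere: HeadSphere | None = None,
    spacing: float = 10.0,
    interior_margin: float = 10.0,
    central_exclusion: float = 0.0,
) -> SourceGrid:
    """Axis-aligned lattice of scan points with ``||p - c|| <= radius - margin``.

    The lattice is centered on the sphere center and ordered lexicographically
    in (x, y, z).  ``central_exclusion`` additionally drops points closer than
    that distance to the center: a spherical conductor is magnetically
    near-silent around its center, so scanning there is ill-posed (the
    experiment harness excludes a 25 mm core by default).
    """
    sphere = sphere or HeadSphere()
    if not 0 < spacing < 2 * sphere.radius:
        raise ValueError("spacing must be in (0, 2*radius)")
    r_eff = sphere.radius - interior_margin
    if r_eff <= 0:
        raise ValueError("interior_margin leaves no interior volume")
    n = int(math.floor(r_eff / spacing))
    offs = spacing * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + sphere.center
    depth = np.linalg.norm(pts - sphere.center, axis=1)
    keep = (depth <= r_eff) & (depth >= central_exclusion)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError("no lattice point inside the sphere at this spacing/margin")
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return SourceGrid(points=pts[order], spacing=spacing)


def subsample_grid(grid: SourceGrid, step: int) -> np.ndarray:
    """Every ``step``-th grid index starting at the first point.

    Yields floor((P-1)/step) + 1 indices.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    return np.arange(0, grid.n_points, step)


def channel_type_mask(array: SensorArray, channels: str = "grads") -> np.ndarray:
    """Boolean channel selector: 'grads' (planar gradiometers), 'mags', or 'all'."""
    t = array.channel_types
    if channels == "all":
        return np.ones(array.n_channels, dtype=bool)
    if channels == "mags":
        return t == "magnetometer"
    if channels == "grads":
        return (t == "planar_grad_1") | (t == "planar_grad_2")
    raise ValueError("channels must be one of 'grads', 'mags', 'all'")


# ---------------------------------------------------------------------------
# plain-text I/O

_LAYOUT_FIELDS = [
    "site_id", "channel_id", "type", "x", "y", "z",
    "ox", "oy", "oz", "bx", "by", "bz", "baseline_mm", "region",
]


def save_layout_csv(path, array: SensorArray, partition: RegionPartition | None = None) -> None:
    labels = partition.labels if partition is not None else [""] * array.n_channels
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LAYOUT_FIELDS)
        for m in range(array.n_channels):
            w.writerow([
                int(array.site_index[m]), m, array.channel_types[m],
                *array.channel_positions[m], *array.channel_orientations[m],
                *array.baseline_dir[m], array.baseline_mm[m], labels[m],
            ])


def load_layout_csv(path) -> tuple[SensorArray, RegionPartition | None]:
    rows = list(csv.DictReader(open(path, newline="")))
    M = len(rows)
    pos = np.array([[float(r[c]) for c in ("x", "y", "z")] for r in rows])
    ori = np.array([[float(r[c]) for c in ("ox", "oy", "oz")] for r in rows])
    bdir = np.array([[float(r[c]) for c in ("bx", "by", "bz")] for r in rows])
    bmm = np.array([float(r["baseline_mm"]) for r in rows])
    types = np.array([r["type"] for r in rows], dtype=object)
    site_index = np.array([int(r["site_id"]) for r in rows])
    sites_seen: dict[int, np.ndarray] = {}
    for r, p in zip(rows, pos):
        sites_seen.setdefault(int(r["site_id"]), p)
    sites = np.array([sites_seen[s] for s in sorted(sites_seen)])
    array = SensorArray(sites, pos, ori, types, site_index, bdir, bmm)
    labels = np.array([r["region"] for r in rows], dtype=object)
    part = RegionPartition(labels=labels) if all(labels != "") else None
    return array, part


def save_grid_csv(path, grid: SourceGrid) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "x", "y", "z"])
        for i, p in enumerate(grid.points):
            w.writerow([i, *p])


def load_grid_csv(path, spacing: float | None = None) -> SourceGrid:
    rows = list(csv.DictReader(open(path, newline="")))
    pts = np.array([[float(r[c]) for c in ("x", "y", "z")] for r in rows])
    if spacing is None:
        # infer the lattice pitch from the smallest nonzero coordinate gap
        diffs = [np.diff(np.unique(pts[:, a])) for a in range(3)]
        diffs = np.concatenate([d for d in diffs if d.size])
        spacing = float(diffs.min()) if diffs.size else 1.0
    return SourceGrid(points=pts, spacing=spacing)
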
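"""Voxelized sphere phantoms and dwell-time-weighted averaged density grids.

Coordinate convention: right-handed isocenter frame in cm, +y = superior
(the motion axis), +z = towards the source.  Density is water-relative
(water = 1.0).

The "averaged tumor" is the arithmetic mean of the sphere's occupancy over
all gated breathing samples, each displaced along sup-inf by the sampled
surrogate position.  Because the breathing curve is sampled uniformly in
time, each gated sample contributes equal weight, so the average is
implicitly dwell-time weighted -- positions where the tumor lingers
accumulate more mass than positions it sweeps through quickly.  This is
exactly what distinguishes the construction from a ten-phase 4DCT average.

Partial-volume voxelization uses 3x3x3 supersampling: a voxel's value is
the occupied fraction of its 27 subcells.  Displacements are applied on the
supersampled y-grid with linear sub-bin interpolation, so the averaging is
exact for displacements on the fine grid and first-order accurate (to a
third of a voxel) in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, EmptyGateError, InvalidArgumentError

__all__ = [
    "SpherePhantom",
    "RodPhantom",
    "GridSpec",
    "DensityGrid",
    "grid_for_motion",
    "sphere_occupancy",
    "averaged_density",
    "save_density_grid",
    "load_density_grid",
]

SUPERSAMPLE = 3  # subcells per voxel edge for partial-volume estimation
DEFAULT_SPACING = 0.1  # cm, isotropic
DEFAULT_MARGIN = 0.3  # cm of clearance around the phantom's motion envelope


@dataclass(frozen=True)
class SpherePhantom:
    """Spherical tumor phantom: diameter in cm, water-relative density."""

    diameter: float
    relative_density: float = 1.0
    rest_center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0.0:
            raise InvalidArgumentError("sphere diameter must be positive")
        if self.relative_density < 0.0:
            raise InvalidArgumentError("relative density must be non-negative")
        object.__setattr__(self, "rest_center", tuple(float(c) for c in self.rest_center))

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass(frozen=True)
class RodPhantom:
    """Static support rod: an infinite cylinder clipped to the grid.

    Default density 0.2 reflects a rod printed at 20% infill to minimise
    beam attenuation.  The rod does not move with the tumor.
    """

    radius: float
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    relative_density: float = 0.2
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius < 0.0:
            raise InvalidArgumentError("rod radius must be non-negative")
        if self.relative_density < 0.0:
            raise InvalidArgumentError("relative density must be non-negative")
        a = np.asarray(self.axis, dtype=np.float64)
        norm = float(np.linalg.norm(a))
        if norm == 0.0:
            raise InvalidArgumentError("rod axis must be a non-zero vector")
        object.__setattr__(self, "axis", tuple(a / norm))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: corner origin, isotropic spacing, shape (nx, ny, nz)."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0.0:
            raise InvalidArgumentError("grid spacing must be positive")
        if any(s < 1 for s in self.shape):
            raise InvalidArgumentError("grid shape must be at least 1 voxel per axis")
        object.__setattr__(self, "origin", tuple(float(c) for c in self.origin))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def extent(self) -> tuple[tuple[float, float], ...]:
        """(lo, hi) physical bounds per axis."""
        return tuple(
            (o, o + n * self.spacing) for o, n in zip(self.origin, self.shape)
        )

    def centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing


@dataclass
class DensityGrid:
    """3D grid of water-relative density on a GridSpec lattice."""

    origin: tuple[float, float, float]
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidArgumentError("density grid values must be 3D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0.0):
            raise InvalidArgumentError("density values must be finite and non-negative")
        self.origin = tuple(float(c) for c in self.origin)
        self.spacing = float(self.spacing)

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.origin, self.spacing, self.values.shape)

    def total_mass(self) -> float:
        """Integrated density, cm^3 of water-equivalent volume."""
        return float(self.values.sum() * self.spacing**3)


def grid_for_motion(
    sphere: SpherePhantom,
    displacements=(0.0,),
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
) -> GridSpec:
    """Smallest grid containing the sphere over its sup-inf motion range."""
    d = np.asarray(displacements, dtype=np.float64)
    if d.size == 0:
        d = np.zeros(1)
    r = sphere.radius
    cx, cy, cz = sphere.rest_center
    lo = np.array([cx - r, cy + d.min() - r, cz - r]) - margin
    hi = np.array([cx + r, cy + d.max() + r, cz + r]) + margin
    shape = np.ceil((hi - lo) / spacing - 1e-9).astype(int)
    # center the requested extent inside the integer-sized grid
    origin = 0.5 * (lo + hi) - 0.5 * shape * spacing
    return GridSpec(tuple(origin), spacing, tuple(shape))


def _check_sphere_inside(sphere: SpherePhantom, spec: GridSpec, dmin: float, dmax: float) -> None:
    r = sphere.radius
    c = sphere.rest_center
    ext = spec.extent
    slack = 1e-9
    lo = (c[0] - r, c[1] + dmin - r, c[2] - r)
    hi = (c[0] + r, c[1] + dmax + r, c[2] + r)
    for ax in range(3):
        if lo[ax] < ext[ax][0] - slack or hi[ax] > ext[ax][1] + slack:
            raise BoundsError(
                "sphere (over its motion range) does not fit inside the density grid"
            )


# cache of supersampled sphere profiles keyed by (sphere geometry, grid spec);
# the profile is fine along y (the motion axis) and already averaged over the
# x/z subsamples, which commutes with the y-displacement averaging below.
_FINE_CACHE: dict[tuple, np.ndarray] = {}
_FINE_CACHE_MAX = 8


def _fine_profile(sphere: SpherePhantom, spec: GridSpec) -> np.ndarray:
    """Occupancy array of shape (nx, ny*SS, nz): fine in y, x/z-subsample mean."""
    key = (sphere.diameter, sphere.rest_center, spec)
    cached = _FINE_CACHE.get(key)
    if cached is not None:
        return cached
    ss = SUPERSAMPLE
    h = spec.spacing
    nx, ny, nz = spec.shape
    r2 = sphere.radius**2
    cx, cy, cz = sphere.rest_center
    sub = ((np.arange(ss) + 0.5) / ss - 0.5) * h  # subcell offsets within a voxel
    x = spec.centers(0) - cx
    z = spec.centers(2) - cz
    yf = spec.origin[1] + (np.arange(ny * ss) + 0.5) * (h / ss) - cy
    yf2 = yf**2
    out = np.zeros((nx, ny * ss, nz), dtype=np.float64)
    for ox in sub:
        a2 = (x + ox) ** 2
        for oz in sub:
            c2 = (z + oz) ** 2
            out += (
                a2[:, None, None] + yf2[None, :, None] + c2[None, None, :] <= r2
            )
    out /= ss * ss
    if len(_FINE_CACHE) >= _FINE_CACHE_MAX:
        _FINE_CACHE.pop(next(iter(_FINE_CACHE)))
    _FINE_CACHE[key] = out
    return out


def _coarsen_y(fine: np.ndarray) -> np.ndarray:
    nx, nyf, nz = fine.shape
    ny = nyf // SUPERSAMPLE
    return fine.reshape(nx, ny, SUPERSAMPLE, nz).mean(axis=2)


def sphere_occupancy(sphere: SpherePhantom, spec: GridSpec) -> DensityGrid:
    """Partial-volume voxelization of a static sphere.

    Each voxel's value is ``relative_density`` times the fraction of the
    voxel inside the sphere, estimated by 3x3x3 supersampling.
    """
    _check_sphere_inside(sphere, spec, 0.0, 0.0)
    vals = _coarsen_y(_fine_profile(sphere, spec)) * sphere.relative_density
    return DensityGrid(spec.origin, spec.spacing, vals)


def _rod_occupancy(rod: RodPhantom, spec: GridSpec) -> np.ndarray:
    ss = SUPERSAMPLE
    h = spec.spacing
    sub = ((np.arange(ss) + 0.5) / ss - 0.5) * h
    axes = [spec.centers(i) - rod.center[i] for i in range(3)]
    a = np.asarray(rod.axis)
    r2 = rod.radius**2
    nx, ny, nz = spec.shape
    out = np.zeros((nx, ny, nz), dtype=np.float64)
    for ox in sub:
        X = axes[0] + ox
        for oy in sub:
            Y = axes[1] + oy
            for oz in sub:
                Z = axes[2] + oz
                dot = (
                    X[:, None, None] * a[0]
                    + Y[None, :, None] * a[1]
                    + Z[None, None, :] * a[2]
                )
                d2 = (
                    X[:, None, None] ** 2
                    + Y[None, :, None] ** 2
                    + Z[None, None, :] ** 2
                    - dot**2
                )
                out += d2 <= r2
    return out / ss**3 * rod.relative_density


def _displacement_kernel(displacements: np.ndarray, fine_step: float):
    """Offsets (fine-grid steps) and dwell weights with linear sub-bin splitting."""
    u = displacements / fine_step
    i0 = np.floor(u).astype(np.int64)
    frac = u - i0
    lo = int(i0.min())
    hi = int(i0.max()) + 1
    w = np.zeros(hi - lo + 1, dtype=np.float64)
    np.add.at(w, i0 - lo, (1.0 - frac))
    np.add.at(w, i0 - lo + 1, frac)
    w /= displacements.size
    offsets = np.arange(lo, hi + 1)
    keep = w > 0.0
    return offsets[keep], w[keep]


def averaged_density(
    sphere: SpherePhantom,
    curve=None,
    mask=None,
    spec: GridSpec | None = None,
    rod: RodPhantom | None = None,
    displacements=None,
    spacing: float = DEFAULT_SPACING,
) -> DensityGrid:
    """Dwell-time-weighted average of the sphere over gated breathing positions.

    The sphere is displaced along sup-inf (+y) by each gated sample's
    surrogate position and the occupancies are averaged with equal weight
    per sample.  Either pass ``curve`` and a boolean gated-sample ``mask``,
    or pass ``displacements`` directly.  The static rod, if given, is added
    after averaging.
    """
    if displacements is None:
        if curve is None or mask is None:
            raise InvalidArgumentError("pass either (curve, mask) or displacements")
        mask = np.asarray(mask, dtype=bool)
        displacements = curve.positions[mask]
    displacements = np.asarray(displacements, dtype=np.float64)
    if displacements.size == 0:
        raise EmptyGateError("gating window selects no breathing samples")
    if spec is None:
        spec = grid_for_motion(sphere, displacements, spacing)
    _check_sphere_inside(sphere, spec, float(displacements.min()), float(displacements.max()))
    fine_step = spec.spacing / SUPERSAMPLE
    offsets, weights = _displacement_kernel(displacements, fine_step)
    # the rest-position sphere may stick out of a grid sized for the displaced
    # range only; voxelize it on a y-padded grid and crop while shifting
    m_lo, m_hi = int(offsets.min()), int(offsets.max())
    pad_below = -(-max(0, m_hi) // SUPERSAMPLE)  # voxels, ceil division
    pad_above = -(-max(0, -m_lo) // SUPERSAMPLE)
    nx, ny, nz = spec.shape
    ext_spec = GridSpec(
        (spec.origin[0], spec.origin[1] - pad_below * spec.spacing, spec.origin[2]),
        spec.spacing,
        (nx, ny + pad_below + pad_above, nz),
    )
    fine_ext = _fine_profile(sphere, ext_spec)
    nyf = ny * SUPERSAMPLE
    base = pad_below * SUPERSAMPLE  # fine index of the grid's y origin in ext
    out = np.zeros((nx, nyf, nz), dtype=np.float64)
    for m, w in zip(offsets, weights):
        lo = base - int(m)
        out += w * fine_ext[:, lo : lo + nyf, :]
    vals = _coarsen_y(out) * sphere.relative_density
    if rod is not None:
        vals = vals + _rod_occupancy(rod, spec)
    return DensityGrid(spec.origin, spec.spacing, vals)


def save_density_grid(grid: DensityGrid, path) -> None:
    """Export as a flat float32 binary grid plus a JSON sidecar."""
    path = str(path)
    grid.values.astype(np.float32).tofile(path)
    sidecar = {
        "origin_cm": list(grid.origin),
        "spacing_cm": grid.spacing,
        "shape": list(grid.values.shape),
        "dtype": "float32",
        "order": "C (x, y, z)",
    }
    with open(path + ".json", "w", encoding="utf-8") as f:
        json.dump(sidecar, f, indent=2)
        f.write("\n")


def load_density_grid(path) -> DensityGrid:
    path = str(path)
    with open(path + ".json", "r", encoding="utf-8") as f:
        sidecar = json.load(f)
    shape = tuple(sidecar["shape"])
    vals = np.fromfile(path, dtype=np.float32)
    if vals.size != int(np.prod(shape)):
        raise InvalidArgumentError("binary grid size does not match its sidecar shape")
    return DensityGrid(tuple(sidecar["origin_cm"]), sidecar["spacing_cm"], vals.reshape(shape))
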
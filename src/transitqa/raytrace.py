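"""Radiological path lengths through a density grid via Siddon's algorithm.

Each ray from the point source to a detector pixel is traversed with exact
parametric plane crossings (no sampling): the intersection parameters with
every voxel-boundary plane inside the grid are collected, sorted, and each
inter-crossing segment is attributed to the voxel containing its midpoint.
Midpoint ownership realises the standard half-open Siddon convention (a
crossing point belongs to the next voxel along the ray) without double
counting.  The radiological length is the sum of segment length times voxel
density, in water-equivalent cm.

Beam geometry: point source at (0, 0, SAD) in the isocenter frame; the
detector plane sits at z = SAD - SID.  Pixel spacing is expressed at the
isocenter plane, where gamma criteria are also defined; with SID = SAD the
image is referenced directly to the isocenter plane.  Rows map to -y
(superior at the top of the image), columns to +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InvalidArgumentError
from .phantom import DensityGrid

__all__ = ["BeamGeometry", "ThicknessMap", "siddon_path", "thickness_map"]


@dataclass(frozen=True)
class BeamGeometry:
    """Projective frame tying the density grid to the portal image.

    Attributes
    ----------
    sad : float
        Source-to-isocenter distance, cm.
    sid : float
        Source-to-detector distance, cm (``sid >= sad``).
    pixel_pitch_iso : float
        Pixel spacing expressed at the isocenter plane, cm.
    shape : (rows, cols)
        Image dimensions.
    center_px : (row, col)
        Pixel coordinates of the beam axis; defaults to the image center.
    """

    sad: float = 100.0
    sid: float = 100.0
    pixel_pitch_iso: float = 0.1
    shape: tuple[int, int] = (256, 256)
    center_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.sid >= self.sad > 0.0):
            raise InvalidArgumentError("require SID >= SAD > 0")
        if self.pixel_pitch_iso <= 0.0:
            raise InvalidArgumentError("pixel pitch must be positive")
        object.__setattr__(self, "shape", (int(self.shape[0]), int(self.shape[1])))
        if self.center_px is None:
            object.__setattr__(
                self,
                "center_px",
                ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0),
            )
        else:
            object.__setattr__(
                self, "center_px", (float(self.center_px[0]), float(self.center_px[1]))
            )

    def pixel_positions_iso(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center (x, y) coordinates at the isocenter plane, cm."""
        rows, cols = self.shape
        cr, cc = self.center_px
        x = (np.arange(cols) - cc) * self.pixel_pitch_iso
        y = (cr - np.arange(rows)) * self.pixel_pitch_iso
        return np.meshgrid(x, y)  # X[row, col], Y[row, col]

    def source_point(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.sad])

    def detector_points(self) -> np.ndarray:
        """Physical pixel positions on the detector plane, shape (rows*cols, 3)."""
        X, Y = self.pixel_positions_iso()
        scale = self.sid / self.sad
        z = self.sad - self.sid
        pts = np.empty((X.size, 3), dtype=np.float64)
        pts[:, 0] = X.ravel() * scale
        pts[:, 1] = Y.ravel() * scale
        pts[:, 2] = z
        return pts


@dataclass
class ThicknessMap:
    """Per-pixel radiological thickness, cm, aligned with the portal image grid."""

    values: np.ndarray
    geom: BeamGeometry


@njit(cache=False)
def _trace_rays(origin, h, dens, src, tgts, out):  # pragma: no cover - numba
    nx, ny, nz = dens.shape
    dims0 = nx
    dims1 = ny
    dims2 = nz
    nmax = nx + ny + nz + 4
    alphas = np.empty(nmax)
    sv = np.empty(3)
    dv = np.empty(3)
    dims = np.empty(3, dtype=np.int64)
    dims[0] = dims0
    dims[1] = dims1
    dims[2] = dims2
    for r in range(tgts.shape[0]):
        for ax in range(3):
            sv[ax] = src[ax]
            dv[ax] = tgts[r, ax] - src[ax]
        amin = 0.0
        amax = 1.0
        ok = True
        for ax in range(3):
            b_lo = origin[ax]
            b_hi = origin[ax] + dims[ax] * h
            d = dv[ax]
            if abs(d) < 1e-12:
                if sv[ax] <= b_lo or sv[ax] >= b_hi:
                    ok = False
                    break
            else:
                a0 = (b_lo - sv[ax]) / d
                a1 = (b_hi - sv[ax]) / d
                lo = a0 if a0 < a1 else a1
                hi = a1 if a0 < a1 else a0
                if lo > amin:
                    amin = lo
                if hi < amax:
                    amax = hi
        if (not ok) or amax <= amin + 1e-15:
            out[r] = 0.0
            continue
        cnt = 0
        alphas[cnt] = amin
        cnt += 1
        alphas[cnt] = amax
        cnt += 1
        for ax in range(3):
            d = dv[ax]
            if abs(d) < 1e-12:
                continue
            b_lo = origin[ax]
            # voxel-boundary planes b_lo + k*h crossed strictly inside (amin, amax)
            if d > 0.0:
                kmin = int(math.floor((sv[ax] + amin * d - b_lo) / h)) + 1
                kmax = int(math.ceil((sv[ax] + amax * d - b_lo) / h)) - 1
            else:
                kmin = int(math.floor((sv[ax] + amax * d - b_lo) / h)) + 1
                kmax = int(math.ceil((sv[ax] + amin * d - b_lo) / h)) - 1
            if kmin < 0:
                kmin = 0
            if kmax > dims[ax]:
                kmax = dims[ax]
            for k in range(kmin, kmax + 1):
                a = (b_lo + k * h - sv[ax]) / d
                if amin < a < amax:
                    alphas[cnt] = a
                    cnt += 1
        seg = np.sort(alphas[:cnt].copy())
        length = math.sqrt(dv[0] * dv[0] + dv[1] * dv[1] + dv[2] * dv[2])
        acc = 0.0
        for k in range(cnt - 1):
            da = seg[k + 1] - seg[k]
            if da <= 1e-15:
                continue
            am = 0.5 * (seg[k] + seg[k + 1])
            ix = int(math.floor((sv[0] + am * dv[0] - origin[0]) / h))
            iy = int(math.floor((sv[1] + am * dv[1] - origin[1]) / h))
            iz = int(math.floor((sv[2] + am * dv[2] - origin[2]) / h))
            if 0 <= ix < dims0 and 0 <= iy < dims1 and 0 <= iz < dims2:
                acc += da * length * dens[ix, iy, iz]
        out[r] = acc


def _trace(grid: DensityGrid, src: np.ndarray, tgts: np.ndarray) -> np.ndarray:
    out = np.empty(tgts.shape[0], dtype=np.float64)
    _trace_rays(
        np.asarray(grid.origin, dtype=np.float64),
        grid.spacing,
        grid.values,
        np.ascontiguousarray(src, dtype=np.float64),
        np.ascontiguousarray(tgts, dtype=np.float64),
        out,
    )
    return out


def siddon_path(grid: DensityGrid, source, target) -> float:
    """Radiological length, cm, of the segment source -> target through the grid.

    The source must lie outside the grid; a ray missing the grid entirely
    contributes 0.
    """
    src = np.asarray(source, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if src.shape != (3,) or tgt.shape != (3,):
        raise InvalidArgumentError("source and target must be 3-vectors")
    if float(np.linalg.norm(tgt - src)) < 1e-12:
        raise InvalidArgumentError("degenerate zero-length ray")
    ext = grid.spec.extent
    if all(ext[i][0] < src[i] < ext[i][1] for i in range(3)):
        raise InvalidArgumentError("ray source must lie outside the density grid")
    return float(_trace(grid, src, tgt[None, :])[0])


def thickness_map(grid: DensityGrid, geom: BeamGeometry) -> ThicknessMap:
    """Radiological thickness seen by every detector pixel (divergent beam)."""
    src = geom.source_point()
    ext = grid.spec.extent
    if all(ext[i][0] < src[i] < ext[i][1] for i in range(3)):
        raise InvalidArgumentError("beam source lies inside the density grid")
    tgts = geom.detector_points()
    vals = _trace(grid, src, tgts).reshape(geom.shape)
    return ThicknessMap(vals, geom)
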
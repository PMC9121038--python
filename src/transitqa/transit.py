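"""Transit portal dose prediction through the averaged moving phantom.

The transit portal dose behind an object factorises as

    pI_ph(x, y) = pI_air(x, y) * T(t(x, y), FS) * OAR(x, y, t) * G(x, y, t, FS, g)

where pI_air is the in-air portal dose, t the radiological thickness along
the pixel's ray, FS the equivalent field size and g the air gap.  T is the
empirical two-exponential transmission factor

    T(t, FS) = (A * exp(-B t) + C * exp(-D t)) / S0,

whose per-field-size coefficients come from a commissioning fit and are
configuration here, not constants; the default single-exponential with
B = 0.0459 cm^-1 is a physically plausible normalised 6 MV water
attenuation.  The off-axis-ratio factor OAR and air-gap factor G are
identity by default -- for desk-scale phantoms their effect is negligible --
but the hooks accept full per-pixel maps so the factorisation stays intact.

Two forward models are provided:

* :func:`predict_pd` -- the QA prediction: T evaluated on the thickness map
  of the dwell-time-averaged phantom (T of the mean thickness).
* :func:`simulate_measured_pd` -- a synthetic stand-in for the physical
  EPID acquisition: the attenuation is resolved in time, averaging T over
  the thickness maps of each gated instantaneous phantom position (mean of
  T).  The two agree exactly for a static phantom and differ by a Jensen
  gap (mean-of-T >= T-of-mean for convex T) for moving ones, which is
  precisely the model error the gamma comparison then quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breathing import BreathingCurve, GatingWindow, gating_mask
from .errors import EmptyGateError, GeometryError, InvalidArgumentError
from .phantom import (
    DEFAULT_SPACING,
    RodPhantom,
    SpherePhantom,
    averaged_density,
    grid_for_motion,
    sphere_occupancy,
)
from .raytrace import BeamGeometry, thickness_map, _trace

__all__ = [
    "PortalImage",
    "TransmissionParams",
    "transmission",
    "predict_pd",
    "simulate_measured_pd",
]


@dataclass
class PortalImage:
    """2D portal dose grid with its beam geometry.

    Values are in arbitrary calibrated units; gamma analysis normalises
    globally, so only relative dose matters.
    """

    values: np.ndarray
    geom: BeamGeometry
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geom.shape:
            raise GeometryError(
                f"image shape {self.values.shape} does not match geometry {self.geom.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0.0):
            raise InvalidArgumentError("portal dose values must be finite and >= 0")


@dataclass(frozen=True)
class TransmissionParams:
    """Coefficients of the two-exponential transmission factor for one field size.

    ``A`` and ``C`` are dimensionless amplitudes, ``B`` and ``D`` attenuation
    coefficients in cm^-1, ``s0`` the zero-thickness normalisation, and
    ``field_size`` the equivalent square side in cm that selects this
    coefficient set.
    """

    A: float = 1.0
    B: float = 0.0459
    C: float = 0.0
    D: float = 0.0
    s0: float = 1.0
    field_size: float = 10.0

    def __post_init__(self) -> None:
        if self.A + self.C <= 0.0:
            raise InvalidArgumentError("require A + C > 0")
        if self.B < 0.0 or self.D < 0.0:
            raise InvalidArgumentError("attenuation coefficients must be >= 0")
        if self.s0 <= 0.0:
            raise InvalidArgumentError("normalisation S0 must be positive")


def transmission(t, params: TransmissionParams = TransmissionParams()):
    """Transmission factor T(t) for radiological thickness t (cm).

    Strictly positive, and non-increasing in t for B, D >= 0.  With
    ``s0 = A + C`` it is normalised to T(0) = 1.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0.0):
        raise InvalidArgumentError("radiological thickness must be >= 0")
    return (params.A * np.exp(-params.B * t) + params.C * np.exp(-params.D * t)) / params.s0


def _apply_hooks(values: np.ndarray, pIair: PortalImage, oar, air_gap) -> np.ndarray:
    for factor in (oar, air_gap):
        if factor is not None:
            factor = np.asarray(factor, dtype=np.float64)
            if factor.shape != pIair.geom.shape:
                raise GeometryError("per-pixel factor map does not match image shape")
            values = values * factor
    return values


def _gated_displacements(curve: BreathingCurve, window: GatingWindow) -> np.ndarray:
    mask = gating_mask(curve, window)
    if not mask.any():
        raise EmptyGateError(f"window {window} has no dwell time on this curve")
    return curve.positions[mask]


def predict_pd(
    pIair: PortalImage,
    curve: BreathingCurve,
    window: GatingWindow,
    sphere: SpherePhantom,
    params: TransmissionParams = TransmissionParams(),
    rod: RodPhantom | None = None,
    spec=None,
    spacing: float = DEFAULT_SPACING,
    oar=None,
    air_gap=None,
) -> PortalImage:
    """Predicted transit portal dose through the averaged gated phantom.

    Builds the dwell-time-weighted averaged density over the gated samples,
    ray-traces its thickness map, and returns ``pIair * T(t)``.  The density
    grid defaults to one spanning the curve's full motion range, so every
    window-conditional prediction on the same curve shares one voxelization.
    """
    disp = _gated_displacements(curve, window)
    if spec is None:
        spec = grid_for_motion(sphere, curve.positions, spacing)
    avg = averaged_density(sphere, spec=spec, rod=rod, displacements=disp)
    tmap = thickness_map(avg, pIair.geom)
    vals = pIair.values * transmission(tmap.values, params)
    vals = _apply_hooks(vals, pIair, oar, air_gap)
    return PortalImage(vals, pIair.geom, label=f"predicted {window}")


def simulate_measured_pd(
    pIair: PortalImage,
    executed_curve: BreathingCurve,
    true_window: GatingWindow,
    sphere: SpherePhantom,
    params: TransmissionParams = TransmissionParams(),
    rod: RodPhantom | None = None,
    spacing: float = DEFAULT_SPACING,
    oar=None,
    air_gap=None,
) -> PortalImage:
    """Forward-simulated "measured" transit portal dose.

    The attenuation is resolved in time: for each gated sample the sphere is
    displaced to that sample's position, its thickness map is traced, and
    the per-pixel transmissions are averaged -- the EPID integrates dose
    while the phantom moves, so it records the mean of T, not T of the mean.
    Geometrically, displacing the sphere by d and tracing from the fixed
    source equals tracing the static sphere with source and pixel both
    shifted by -d along sup-inf, which is how it is computed.
    """
    disp = _gated_displacements(executed_curve, true_window)
    static = sphere_occupancy(sphere, grid_for_motion(sphere, (0.0,), spacing))
    geom = pIair.geom
    src0 = geom.source_point()
    tgts0 = geom.detector_points()
    rod_t = None
    if rod is not None:
        from .phantom import DensityGrid, _rod_occupancy

        rod_grid = DensityGrid(
            static.origin, static.spacing, _rod_occupancy(rod, static.spec)
        )
        rod_t = _trace(rod_grid, src0, tgts0)
    mean_T = np.zeros(tgts0.shape[0], dtype=np.float64)
    src = src0.copy()
    tgts = tgts0.copy()
    for d in disp:
        src[1] = src0[1] - d
        tgts[:, 1] = tgts0[:, 1] - d
        t = _trace(static, src, tgts)
        if rod_t is not None:
            t = t + rod_t
        mean_T += transmission(t, params)
    mean_T /= disp.size
    vals = pIair.values * mean_T.reshape(geom.shape)
    vals = _apply_hooks(vals, pIair, oar, air_gap)
    return PortalImage(vals, geom, label=f"simulated measurement {true_window}")
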
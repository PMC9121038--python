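"""Synthetic in-air portal dose fixtures and patient-like breathing traces.

Clinical in-air portal images (integrated VMAT fields) cannot ship with the
package, so two stand-ins are generated: a smooth open field (flat center,
mild radially symmetric falloff, tanh penumbra) and a "patterned" variant
with smooth MLC-like stripes to exercise dose gradients in gamma analysis.
Both are normalised to a maximum of 1.

The patient-like breathing trace is a sum of two incommensurate sinusoids
with a drifting baseline and seeded band-limited jitter -- irregular enough
to exercise retrospective phase assignment, while remaining clearly
synthetic.
"""

from __future__ import annotations

import numpy as np

from .breathing import DEFAULT_DT, BreathingCurve, assign_phases
from .errors import InvalidArgumentError
from .raytrace import BeamGeometry
from .transit import PortalImage

__all__ = ["open_field", "striped_field", "patient_trace"]


def open_field(
    geom: BeamGeometry = BeamGeometry(),
    radius: float = 5.0,
    penumbra: float = 0.4,
    falloff: float = 0.06,
) -> PortalImage:
    """Smooth open-field in-air portal dose at the isocenter plane.

    ``radius`` is the 50% field edge in cm, ``penumbra`` the tanh edge
    width, ``falloff`` the fractional dose droop from axis to field edge.
    """
    if radius <= 0.0 or penumbra <= 0.0:
        raise InvalidArgumentError("field radius and penumbra must be positive")
    X, Y = geom.pixel_positions_iso()
    r = np.hypot(X, Y)
    edge = 0.5 * (1.0 - np.tanh((r - radius) / penumbra))
    flat = np.clip(1.0 - falloff * (r / radius) ** 2, 0.0, None)
    vals = edge * flat
    vals /= vals.max()
    return PortalImage(vals, geom, label="synthetic open field")


def striped_field(
    geom: BeamGeometry = BeamGeometry(),
    stripe_period: float = 2.0,
    depth: float = 0.3,
    radius: float = 5.0,
    penumbra: float = 0.4,
    falloff: float = 0.06,
) -> PortalImage:
    """Open field modulated by smooth MLC-like stripes along x (cm period)."""
    if not (0.0 <= depth < 1.0):
        raise InvalidArgumentError("stripe depth must lie in [0, 1)")
    base = open_field(geom, radius, penumbra, falloff)
    X, _ = geom.pixel_positions_iso()
    stripes = 1.0 - depth * (0.5 + 0.5 * np.cos(2.0 * np.pi * X / stripe_period))
    vals = base.values * stripes
    vals /= vals.max()
    return PortalImage(vals, geom, label="synthetic striped field")


def patient_trace(
    duration: float = 60.0,
    dt: float = DEFAULT_DT,
    period: float = 4.0,
    peak_to_peak: float = 2.0,
    drift: float = 0.15,
    jitter: float = 0.03,
    seed: int = 0,
) -> BreathingCurve:
    """Irregular patient-like breathing trace with retrospective phases.

    Two sinusoids (fundamental plus a weak incommensurate second component),
    a slow baseline drift of amplitude ``drift`` cm and band-limited jitter
    of sd ``jitter`` cm.  Phases are assigned retrospectively by peak
    detection, as for a real surrogate trace.
    """
    if duration < 2.0 * period:
        raise InvalidArgumentError("duration must cover at least two breathing periods")
    n = int(np.floor(duration / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    a = 0.5 * peak_to_peak
    rng = np.random.default_rng(seed)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    pos = a * np.cos(2.0 * np.pi * t / period)
    pos += 0.18 * a * np.cos(2.0 * np.pi * t / (0.37 * period) + phase0)
    pos += drift * np.sin(2.0 * np.pi * t / duration + rng.uniform(0.0, 2.0 * np.pi))
    if jitter > 0.0:
        raw = rng.normal(0.0, 1.0, size=n)
        k = max(3, int(round(0.1 * period / dt)))
        kernel = np.hanning(k)
        kernel /= kernel.sum()
        smooth = np.convolve(raw, kernel, mode="same")
        smooth *= 1.0 / smooth.std()
        pos += jitter * smooth
    return assign_phases(BreathingCurve(t, pos))
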
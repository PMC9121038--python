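"""Simulate a motorized stage's imperfect execution of a commanded breathing curve.

A programmable linear stage driving the tumor phantom does not reproduce the
commanded trace exactly.  Three error mechanisms are modelled, each with a
default magnitude matching bench measurements of such rigs:

* a cumulative time delay that accrues linearly with run time (the executed
  motion is the commanded motion uniformly stretched in time, so a delay
  rate of 0.0655 s per second of run time lengthens every breathing period
  by 6.55%);
* zero-mean Gaussian per-sample positional noise; the default sigma of
  0.0359 cm is chosen so the expected absolute error, sigma*sqrt(2/pi),
  equals the 0.0286 cm mean absolute error observed on hardware;
* over-travel at turning points, where the stage cannot accommodate the
  rapid velocity reversal; the default 0.05 cm is half the 0.1 cm maximal
  positional error observed on hardware.

The executed trace is re-phased retrospectively from its own positions,
emulating a surrogate tracker that watches the marker the stage actually
moves rather than the commanded signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .breathing import BreathingCurve, assign_phases
from .errors import DegenerateTraceError, InvalidArgumentError

__all__ = ["StageErrorModel", "simulate_stage", "period_stretch", "estimate_period"]


@dataclass(frozen=True)
class StageErrorModel:
    """Execution-error model of the motorized stage.

    Attributes
    ----------
    delay_rate : float
        Seconds of lag accumulated per second of run time (>= 0).
    noise_sigma : float
        Standard deviation of zero-mean per-sample positional noise, cm.
    overshoot : float
        Extra excursion applied in the motion direction within +/-2 samples
        of each turning point, cm.
    seed : int
        Seed for the noise generator; same seed gives bit-identical output.
    """

    delay_rate: float = 0.0655
    noise_sigma: float = 0.0359
    overshoot: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delay_rate < 0.0:
            raise InvalidArgumentError("delay_rate must be non-negative")
        if self.noise_sigma < 0.0:
            raise InvalidArgumentError("noise_sigma must be non-negative")
        if self.overshoot < 0.0:
            raise InvalidArgumentError("overshoot must be non-negative")


def period_stretch(model: StageErrorModel) -> float:
    """Fractional period increase produced by the uniform-lag accumulation."""
    return model.delay_rate


def simulate_stage(curve: BreathingCurve, model: StageErrorModel) -> BreathingCurve:
    """Return the trace the stage actually executes for a commanded curve.

    The commanded position is resampled at ``t / (1 + delay_rate)`` (uniform
    time stretch), overshoot is added in the motion direction around each
    turning point, and per-sample Gaussian noise is drawn from the model's
    seed.  Output has the same sampling grid and duration as the input.
    Phases are re-assigned retrospectively from the executed positions; if
    the executed trace is too degenerate to phase (e.g. a constant command),
    the commanded phases are carried over unchanged.
    """
    if model.delay_rate == 0.0 and model.noise_sigma == 0.0 and model.overshoot == 0.0:
        return curve  # identity model
    t = curve.times
    pos = np.interp(t / (1.0 + model.delay_rate), t, curve.positions)
    if model.overshoot > 0.0:
        ptp = float(pos.max() - pos.min())
        if ptp > 0.0:
            prom = 0.1 * ptp
            n = pos.size
            for sign, sig in ((1.0, pos), (-1.0, -pos)):
                pk, _ = find_peaks(sig, prominence=prom)
                for j in pk:
                    lo = max(0, j - 2)
                    hi = min(n, j + 3)
                    pos[lo:hi] += sign * model.overshoot
    if model.noise_sigma > 0.0:
        rng = np.random.default_rng(model.seed)
        pos = pos + rng.normal(0.0, model.noise_sigma, size=pos.size)
    executed = BreathingCurve(t, pos)
    try:
        return assign_phases(executed)
    except DegenerateTraceError:
        return BreathingCurve(t, pos, curve.phases)


def estimate_period(curve: BreathingCurve) -> float:
    """Breathing period estimated from mean-level upward crossings.

    Crossing times are located with linear interpolation between samples,
    which is accurate to far better than a sample for smooth traces; the
    period is the mean interval between consecutive upward crossings.
    """
    pos = curve.positions
    t = curve.times
    x = pos - pos.mean()
    below = x[:-1] < 0.0
    above = x[1:] >= 0.0
    idx = np.nonzero(below & above)[0]
    if idx.size < 2:
        raise DegenerateTraceError("need at least two upward mean-crossings")
    frac = -x[idx] / (x[idx + 1] - x[idx])
    crossings = t[idx] + frac * curve.dt
    return float(np.mean(np.diff(crossings)))
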
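"""Breathing traces, retrospective phase assignment, and cyclic gating windows.

The breathing surrogate is a one-dimensional sup-inf displacement signal
sampled uniformly in time.  Phase runs from 0 to 100% per breathing cycle
with 0% at the inhalation peak and 50% at the exhalation trough.  A gating
window is a cyclic interval of phase parameterised by its center and
half-width; beam-on is permitted while the phase lies inside the window.

Phase is assigned retrospectively, with the whole trace known.  Real-time
predictive phase tracking (as performed by surrogate-camera systems during
delivery) is intentionally not modelled: any drift between the real-time
and the retrospective phase is a discrepancy this QA tool is meant to
detect, not reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateTraceError, FormatError, InvalidArgumentError

__all__ = [
    "DEFAULT_DT",
    "BreathingCurve",
    "GatingWindow",
    "cyclic_distance",
    "make_sinusoid",
    "assign_phases",
    "gating_mask",
    "duty_cycle",
    "read_breathing_csv",
    "write_breathing_csv",
    "read_vxp",
    "write_vxp",
]

#: Default sampling interval, s (typical surrogate-camera frame rate of 30 Hz).
DEFAULT_DT = 1.0 / 30.0

_TIME_TOL = 1e-9  # s, tolerance on uniform sample spacing


def cyclic_distance(a, b, period: float = 100.0):
    """Shortest distance between phases ``a`` and ``b`` on a cycle of ``period``."""
    d = np.abs(np.asarray(a, dtype=np.float64) - b) % period
    return np.minimum(d, period - d)


@dataclass(frozen=True)
class GatingWindow:
    """Cyclic phase interval: gated while cyclic_distance(phase, center) <= half_width.

    Parameters
    ----------
    center : float
        Window center in percent phase, ``0 <= center < 100``.
    half_width : float
        Half-width in percent phase, ``0 < half_width <= 50``.  A half-width
        of 50 spans the full cycle.
    """

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.center < 100.0):
            raise InvalidArgumentError(
                f"window center must lie in [0, 100), got {self.center}"
            )
        if not (0.0 < self.half_width <= 50.0):
            raise InvalidArgumentError(
                f"window half-width must lie in (0, 50], got {self.half_width}"
            )

    @classmethod
    def from_bounds(cls, lo: float, hi: float) -> "GatingWindow":
        """Build a window from its cyclic phase bounds, e.g. ``from_bounds(40, 60)``."""
        width = (hi - lo) % 100.0
        if width == 0.0:
            width = 100.0
        return cls((lo + width / 2.0) % 100.0, width / 2.0)

    @property
    def lo(self) -> float:
        return (self.center - self.half_width) % 100.0

    @property
    def hi(self) -> float:
        return (self.center + self.half_width) % 100.0

    def contains(self, phase) -> np.ndarray:
        """Closed cyclic membership test (boundary phases count as gated)."""
        return cyclic_distance(phase, self.center) <= self.half_width + 1e-9

    def __str__(self) -> str:
        return f"{self.lo:g}%-{self.hi:g}%"


def _wrap_phase(phase: np.ndarray) -> np.ndarray:
    ph = np.asarray(phase, dtype=np.float64) % 100.0
    # a % 100.0 can round to exactly 100.0 for tiny negative inputs
    return np.where(ph >= 100.0, 0.0, ph)


@dataclass(frozen=True)
class BreathingCurve:
    """Uniformly sampled surrogate breathing motion.

    Attributes
    ----------
    times : ndarray
        Sample times, s; strictly increasing with constant spacing.
    positions : ndarray
        Sup-inf surrogate displacement, cm (0 = mean position).
    phases : ndarray or None
        Percent phase in [0, 100) per sample; None until assigned.
    """

    times: np.ndarray
    positions: np.ndarray
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.ascontiguousarray(self.times, dtype=np.float64)
        p = np.ascontiguousarray(self.positions, dtype=np.float64)
        if t.ndim != 1 or t.size < 2:
            raise InvalidArgumentError("a breathing curve needs at least 2 samples")
        if p.shape != t.shape:
            raise InvalidArgumentError("times and positions must have equal length")
        d = np.diff(t)
        if np.any(d <= 0.0) or (d.max() - d.min()) > _TIME_TOL:
            raise InvalidArgumentError(
                "sample times must be strictly increasing with constant spacing"
            )
        if not np.all(np.isfinite(p)):
            raise InvalidArgumentError("positions must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        if self.phases is not None:
            ph = np.ascontiguousarray(self.phases, dtype=np.float64)
            if ph.shape != t.shape:
                raise InvalidArgumentError("phases must have one value per sample")
            if not np.all(np.isfinite(ph)) or np.any(ph < 0.0) or np.any(ph >= 100.0):
                raise InvalidArgumentError("phases must lie in [0, 100)")
            object.__setattr__(self, "phases", ph)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def has_phases(self) -> bool:
        return self.phases is not None

    def with_phases(self, phases) -> "BreathingCurve":
        return BreathingCurve(self.times, self.positions, phases)

    def with_positions(self, positions) -> "BreathingCurve":
        return BreathingCurve(self.times, positions, self.phases)


def make_sinusoid(
    period: float,
    peak_to_peak: float,
    duration: float,
    dt: float = DEFAULT_DT,
) -> BreathingCurve:
    """Pure sinusoidal breathing with analytic phases.

    ``position(t) = (peak_to_peak / 2) * cos(2*pi*t / period)`` so that t = 0
    is an inhalation peak (phase 0) and t = period/2 the exhalation trough
    (phase 50).
    """
    if period <= 0.0:
        raise InvalidArgumentError("period must be positive")
    if dt <= 0.0:
        raise InvalidArgumentError("dt must be positive")
    if peak_to_peak < 0.0:
        raise InvalidArgumentError("peak-to-peak amplitude must be non-negative")
    if duration < period:
        raise InvalidArgumentError("duration must cover at least one breathing period")
    n = int(math.floor(duration / dt + 1e-9)) + 1
    t = np.arange(n, dtype=np.float64) * dt
    pos = 0.5 * peak_to_peak * np.cos(2.0 * np.pi * t / period)
    phase = _wrap_phase(100.0 * ((t / period) % 1.0))
    return BreathingCurve(t, pos, phase)


def _estimate_peak_distance(pos: np.ndarray) -> int:
    """Minimum peak separation in samples, seeded from the autocorrelation peak."""
    x = pos - pos.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    pk, _ = find_peaks(ac)
    lag = int(pk[0]) if pk.size else max(1, x.size // 4)
    return max(1, lag // 2)


def _refine_peak_time(
    times: np.ndarray, pos: np.ndarray, j: int, half_window: int
) -> float:
    """Sub-sample peak time via a local quadratic least-squares fit.

    Falls back to the discrete sample time when the fit is not concave or the
    vertex leaves the fit window (noise-robustness guard).  Peaks detected at
    the trace boundary are never refined.
    """
    n = pos.size
    if j == 0 or j == n - 1:
        return float(times[j])
    lo = max(0, j - half_window)
    hi = min(n, j + half_window + 1)
    if hi - lo < 5:
        return float(times[j])
    tt = times[lo:hi] - times[j]
    c = np.polyfit(tt, pos[lo:hi], 2)
    if c[0] >= 0.0:
        return float(times[j])
    tv = -c[1] / (2.0 * c[0])
    if tv < tt[0] or tv > tt[-1]:
        return float(times[j])
    return float(times[j] + tv)


def assign_phases(curve: BreathingCurve, min_prominence_frac: float = 0.1) -> BreathingCurve:
    """Retrospective phase assignment from detected inhalation peaks.

    Phase is 0 at each detected inhalation peak and grows linearly with time
    to 100 at the next peak.  Samples before the first / after the last peak
    are extrapolated with the adjacent cycle's period.  Peaks are local
    maxima with minimum separation of half the estimated breathing period
    and minimum prominence of ``min_prominence_frac`` of the trace's
    peak-to-peak range; each interior peak is then refined to sub-sample
    precision by a local quadratic fit, which keeps the phase stable under
    per-sample positional noise.
    """
    pos = curve.positions
    t = curve.times
    n = pos.size
    ptp = float(pos.max() - pos.min())
    if not np.isfinite(ptp) or ptp <= 0.0:
        raise DegenerateTraceError("constant trace has no breathing cycles")
    prom = min_prominence_frac * ptp
    distance = _estimate_peak_distance(pos)
    peaks, _ = find_peaks(pos, distance=distance, prominence=prom)
    if peaks.size >= 3:
        distance = max(1, int(round(0.5 * float(np.median(np.diff(peaks))))))
        peaks, _ = find_peaks(pos, distance=distance, prominence=prom)
    peaks = list(int(p) for p in peaks)
    # find_peaks never reports trace endpoints; accept an endpoint as an
    # inhalation peak when it dominates its neighbour and sits near the top
    # of the trace's range.
    top = pos.max() - prom
    if pos[0] >= pos[1] and pos[0] >= top and (not peaks or peaks[0] >= distance):
        peaks.insert(0, 0)
    if pos[-1] >= pos[-2] and pos[-1] >= top and (not peaks or (n - 1 - peaks[-1]) >= distance):
        peaks.append(n - 1)
    if len(peaks) < 2:
        raise DegenerateTraceError("need at least two detectable inhalation peaks")
    interval = float(np.median(np.diff(np.asarray(peaks, dtype=float))))
    half_window = max(3, int(round(0.15 * interval)))
    pk_t = np.array([_refine_peak_time(t, pos, j, half_window) for j in peaks])
    pk_t = np.unique(pk_t)
    if pk_t.size < 2:
        raise DegenerateTraceError("need at least two distinct inhalation peaks")
    # unwrapped phase: 100 per cycle, linear between refined peak times,
    # extrapolated with the adjacent cycle's period outside them
    cyc = 100.0 * np.arange(pk_t.size, dtype=np.float64)
    unwrapped = np.interp(t, pk_t, cyc)
    before = t < pk_t[0]
    after = t > pk_t[-1]
    unwrapped[before] = (t[before] - pk_t[0]) * (100.0 / (pk_t[1] - pk_t[0]))
    unwrapped[after] = cyc[-1] + (t[after] - pk_t[-1]) * (
        100.0 / (pk_t[-1] - pk_t[-2])
    )
    return curve.with_phases(_wrap_phase(unwrapped))


def gating_mask(curve: BreathingCurve, window: GatingWindow) -> np.ndarray:
    """Per-sample boolean mask: True where the sample's phase is gated."""
    if not curve.has_phases:
        raise InvalidArgumentError(
            "curve has no phases; call assign_phases (or use make_sinusoid) first"
        )
    return np.asarray(window.contains(curve.phases))


def duty_cycle(curve: BreathingCurve, window: GatingWindow) -> float:
    """Fraction of breathing time spent inside the gating window, in [0, 1]."""
    m = gating_mask(curve, window)
    if m.size == 0:
        raise InvalidArgumentError("empty curve")
    return float(m.mean())


# ---------------------------------------------------------------------------
# trace file formats
# ---------------------------------------------------------------------------

_CSV_HEADER = "time_s,position_cm"
_CSV_HEADER_PH = "time_s,position_cm,phase_pct"


def write_breathing_csv(curve: BreathingCurve, path) -> None:
    """Write the documented CSV dialect: header then one sample per line."""
    cols = [curve.times, curve.positions]
    header = _CSV_HEADER
    if curve.has_phases:
        cols.append(curve.phases)
        header = _CSV_HEADER_PH
    data = np.column_stack(cols)
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write(header + "\n")
        for row in data:
            f.write(",".join(f"{v:.12g}" for v in row) + "\n")


def read_breathing_csv(path) -> BreathingCurve:
    with open(path, "r", encoding="utf-8") as f:
        header = f.readline().strip()
        if header == _CSV_HEADER:
            ncol = 2
        elif header == _CSV_HEADER_PH:
            ncol = 3
        else:
            raise FormatError(f"unrecognised breathing CSV header: {header!r}")
        data = np.loadtxt(f, delimiter=",", ndmin=2)
    if data.shape[1] != ncol:
        raise FormatError(
            f"breathing CSV has {data.shape[1]} columns but header promises {ncol}"
        )
    phases = data[:, 2] if ncol == 3 else None
    return BreathingCurve(data[:, 0], data[:, 1], phases)


def read_vxp(path) -> BreathingCurve:
    """Read an RPM-style VXP text trace.

    The reader targets the common layout: ``key=value`` header lines, a
    ``Data_layout=`` line naming the comma-separated fields, a ``[Data]``
    marker, then one sample per line.  Amplitude is taken in cm and phase
    in radians (converted to percent as ``100*phi/2pi``); timestamps are in
    milliseconds.
    """
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as f:
        for raw in f:
            line = raw.strip()
            if not line:
                continue
            if not in_data:
                if line.lower() == "[data]":
                    in_data = True
                elif "=" in line:
                    key, _, val = line.partition("=")
                    header[key.strip().lower()] = val.strip()
                continue
            rows.append([float(v) for v in line.split(",")])
    if "data_layout" not in header:
        raise FormatError("VXP file has no Data_layout header line")
    fields = [s.strip().lower() for s in header["data_layout"].split(",")]
    if "amplitude" not in fields or "phase" not in fields:
        raise FormatError("VXP Data_layout must include amplitude and phase")
    if not rows:
        raise FormatError("VXP file has no data rows")
    data = np.asarray(rows, dtype=np.float64)
    if data.shape[1] < len(fields):
        raise FormatError("VXP data rows have fewer columns than Data_layout")
    amp = data[:, fields.index("amplitude")]
    phase_pct = _wrap_phase(100.0 * data[:, fields.index("phase")] / (2.0 * np.pi))
    if "timestamp" in fields:
        times = data[:, fields.index("timestamp")] / 1000.0
        times = times - times[0]
    elif "samples_per_second" in header:
        fs = float(header["samples_per_second"])
        times = np.arange(data.shape[0]) / fs
    else:
        raise FormatError("VXP file carries neither timestamps nor a sample rate")
    return BreathingCurve(times, amp, phase_pct)


def write_vxp(curve: BreathingCurve, path) -> None:
    """Write a VXP-style text trace (synthetic round-trip counterpart of read_vxp)."""
    if not curve.has_phases:
        raise InvalidArgumentError("VXP export requires phases; call assign_phases first")
    with open(path, "w", encoding="utf-8", newline="\n") as f:
        f.write("CRC=0\n")
        f.write("Version=1.6\n")
        f.write("Data_layout=amplitude,phase,timestamp\n")
        f.write(f"Samples_per_second={1.0 / curve.dt:.9g}\n")
        f.write("[Data]\n")
        phase_rad = curve.phases * (2.0 * np.pi / 100.0)
        ts_ms = curve.times * 1000.0
        for a, p, ts in zip(curve.positions, phase_rad, ts_ms):
            f.write(f"{a:.9f},{p:.9f},{ts:.9f}\n")
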
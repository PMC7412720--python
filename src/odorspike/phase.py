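"""Respiratory-phase coupling of spiking activity.

Respiration cycles of variable duration are each mapped to 360 degrees;
spikes receive proportional phase values within their cycle, phases are
binned in 6-degree intervals, and the binned counts are summed as vectors.
The resultant angle theta is the cell's preferred phase and the normalized
resultant length rho its modulation depth; circular uniformity is tested
with the Rayleigh statistic Z = n * rho**2, and significantly modulated
cells are additionally checked for unimodality by comparing the resultant
at the fundamental against the doubled-angle resultant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsignal

from .core import RespirationTrace, SpikeTrain, ValidationError

#: Named phase-origin conventions for cycle boundaries.  "inspiration-onset"
#: places 0 deg at the start of inspiration; "inhalation-exhalation" places
#: 0 deg at the inhalation-to-exhalation transition (half a cycle later).
PHASE_ORIGINS = ("inspiration-onset", "inhalation-exhalation")


@dataclass(frozen=True)
class RespCycleTable:
    """Non-overlapping respiration cycles as (start_s, end_s) rows."""

    starts_s: np.ndarray
    ends_s: np.ndarray
    origin: str = "inspiration-onset"

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        ends = np.asarray(self.ends_s, dtype=float)
        if starts.shape != ends.shape or starts.ndim != 1:
            raise ValidationError("cycle starts and ends must be 1-D, equal length")
        if starts.size:
            if not np.all(ends > starts):
                raise ValidationError("cycle end must exceed cycle start")
            if not np.all(starts[1:] >= ends[:-1] - 1e-12):
                raise ValidationError("cycles must be non-overlapping and sorted")
        if self.origin not in PHASE_ORIGINS:
            raise ValidationError(f"unknown phase origin {self.origin!r}")
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "ends_s", ends)

    def __len__(self) -> int:
        return int(self.starts_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s


@dataclass(frozen=True)
class PhaseSample:
    """Spike phases in degrees within [0, 360)."""

    phases_deg: np.ndarray
    n_dropped: int = 0  # spikes outside any detected cycle

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases_deg, dtype=float)
        if phases.size and ((phases < 0) | (phases >= 360)).any():
            raise ValidationError("phases must lie in [0, 360)")
        object.__setattr__(self, "phases_deg", phases)

    @property
    def n_spikes(self) -> int:
        return int(self.phases_deg.size)


@dataclass(frozen=True)
class PhaseHistogram:
    bin_deg: float
    counts: np.ndarray

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (np.arange(self.counts.size) + 0.5) * self.bin_deg


@dataclass(frozen=True)
class PhaseVector:
    theta_deg: float  # preferred phase in [0, 360); NaN when undefined
    rho: float  # resultant length in [0, 1]
    n: int


@dataclass(frozen=True)
class RayleighResult:
    Z: float
    p: float
    n: int
    significant: bool
    unimodal: Optional[bool] = None


def detect_cycles(
    trace: RespirationTrace,
    passband_hz: tuple[float, float] = (0.5, 15.0),
    min_cycle_s: float = 0.1,
    max_cycle_s: float = 2.0,
    origin: str = "inspiration-onset",
) -> RespCycleTable:
    """Segment a respiration trace into cycles via zero crossings.

    The trace is band-limited with a zero-phase Butterworth filter, then
    rising zero crossings (sub-sample, linearly interpolated) mark cycle
    boundaries.  Cycles with durations outside the physiologic bounds are
    discarded.  The ``origin`` label records what a boundary means for
    downstream phase conventions; it does not change the geometry.
    """
    x = np.asarray(trace.values, dtype=float)
    if x.size < 2 * trace.sample_rate:
        raise ValidationError("trace must be at least 2 s long")
    nyq = trace.sample_rate / 2
    hi = min(passband_hz[1], 0.95 * nyq)
    sos = spsignal.butter(2, [passband_hz[0], hi], btype="bandpass", fs=trace.sample_rate, output="sos")
    y = spsignal.sosfiltfilt(sos, x)

    s = np.sign(y)
    s[s == 0] = 1
    rising = np.nonzero((s[:-1] < 0) & (s[1:] > 0))[0]
    if rising.size < 2:
        warnings.warn("no detectable respiration cycles", stacklevel=2)
        return RespCycleTable(np.array([]), np.array([]), origin=origin)
    # linear interpolation of the crossing instant between samples i and i+1
    frac = -y[rising] / (y[rising + 1] - y[rising])
    crossings = trace.t0 + (rising + frac) / trace.sample_rate

    starts, ends = crossings[:-1], crossings[1:]
    dur = ends - starts
    keep = (dur >= min_cycle_s) & (dur <= max_cycle_s)
    return RespCycleTable(starts[keep], ends[keep], origin=origin)


def rotate_origin(phases_deg: np.ndarray, shift_deg: float) -> np.ndarray:
    """Rotate phases by ``shift_deg`` (mod 360), e.g. 180 to switch between
    inspiration-onset and inhalation-exhalation origin conventions."""
    return np.mod(np.asarray(phases_deg, dtype=float) + shift_deg, 360.0)


def assign_spike_phases(
    train: SpikeTrain,
    cycles: RespCycleTable,
    window: Optional[tuple[float, float]] = None,
) -> PhaseSample:
    """Proportional phase of each spike within its respiration cycle.

    phase = 360 * (t - cycle_start) / cycle_duration.  Spikes outside every
    cycle (or outside ``window`` when given) are dropped and counted.
    A spike is retained whenever its cycle was detected, even if the cycle
    extends past the window edge.
    """
    t = train.times
    if window is not None:
        t = t[(t >= window[0]) & (t < window[1])]
    if len(cycles) == 0 or t.size == 0:
        return PhaseSample(np.array([]), n_dropped=int(t.size))
    idx = np.searchsorted(cycles.starts_s, t, side="right") - 1
    valid = idx >= 0
    inside = np.zeros(t.size, dtype=bool)
    inside[valid] = t[valid] < cycles.ends_s[idx[valid]]
    phases = (
        360.0
        * (t[inside] - cycles.starts_s[idx[inside]])
        / cycles.durations_s[idx[inside]]
    )
    # guard against float rounding at the upper boundary
    phases = np.mod(phases, 360.0)
    return PhaseSample(phases, n_dropped=int(t.size - inside.sum()))


def phase_histogram(sample: PhaseSample, bin_deg: float = 6.0) -> PhaseHistogram:
    n_bins = int(round(360.0 / bin_deg))
    counts, _ = np.histogram(sample.phases_deg, bins=n_bins, range=(0.0, 360.0))
    return PhaseHistogram(bin_deg=bin_deg, counts=counts)


def _resultant(angles_rad: np.ndarray, weights: Optional[np.ndarray] = None) -> tuple[float, float]:
    """(theta_deg, rho) of the normalized weighted vector sum."""
    if weights is None:
        weights = np.ones_like(angles_rad)
    total = weights.sum()
    c = float((weights * np.cos(angles_rad)).sum())
    s = float((weights * np.sin(angles_rad)).sum())
    rho = math.hypot(c, s) / total
    theta = math.degrees(math.atan2(s, c)) % 360.0
    return theta, min(rho, 1.0)


def phase_vector(sample: PhaseSample, bin_deg: float = 6.0) -> PhaseVector:
    """Preferred phase and modulation depth from the binned phase histogram.

    One vector per bin (angle = bin center, magnitude = bin count); theta
    and rho come from the vector sum with rho normalized by the spike count.
    """
    if sample.n_spikes == 0:
        return PhaseVector(theta_deg=float("nan"), rho=float("nan"), n=0)
    hist = phase_histogram(sample, bin_deg)
    theta, rho = _resultant(
        np.radians(hist.bin_centers_deg), hist.counts.astype(float)
    )
    return PhaseVector(theta_deg=theta, rho=rho, n=sample.n_spikes)


def rayleigh_test(vector: PhaseVector, alpha: float = 0.01) -> RayleighResult:
    """Rayleigh test of circular uniformity from a resultant vector.

    Z = n * rho**2; the p-value uses the standard small-sample closed-form
    correction of exp(-Z).  Requires n >= 4.
    """
    n, rho = vector.n, vector.rho
    if n < 4 or not np.isfinite(rho):
        return RayleighResult(Z=float("nan"), p=float("nan"), n=n, significant=False)
    R = n * rho
    Z = n * rho**2
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    p = min(max(p, 0.0), 1.0)
    return RayleighResult(Z=float(Z), p=float(p), n=n, significant=bool(p < alpha))


def check_unimodality(sample: PhaseSample, bin_deg: float = 6.0) -> bool:
    """True when the phase distribution is dominated by a single mode.

    Compares the binned resultant length at the fundamental (R1) with the
    resultant of doubled angles (R2); a bimodal antipodal distribution has
    R2 >> R1.  Returns R1 >= R2.
    """
    if sample.n_spikes == 0:
        return True
    hist = phase_histogram(sample, bin_deg)
    angles = np.radians(hist.bin_centers_deg)
    w = hist.counts.astype(float)
    _, r1 = _resultant(angles, w)
    _, r2 = _resultant(np.mod(2 * angles, 2 * math.pi), w)
    return bool(r1 >= r2)


def cell_phase_stats(
    train: SpikeTrain,
    cycles: RespCycleTable,
    windows: Sequence[tuple[float, float]],
    bin_deg: float = 6.0,
    alpha: float = 0.01,
) -> tuple[PhaseVector, RayleighResult, PhaseSample]:
    """Pooled phase statistics for one cell over a set of analysis windows."""
    phases = []
    dropped = 0
    for w in windows:
        s = assign_spike_phases(train, cycles, w)
        phases.append(s.phases_deg)
        dropped += s.n_dropped
    sample = PhaseSample(
        np.concatenate(phases) if phases else np.array([]), n_dropped=dropped
    )
    vec = phase_vector(sample, bin_deg)
    ray = rayleigh_test(vec, alpha)
    unimodal = check_unimodality(sample, bin_deg) if ray.significant else None
    ray = RayleighResult(Z=ray.Z, p=ray.p, n=ray.n, significant=ray.significant, unimodal=unimodal)
    return vec, ray, sample


def population_mean_phase(thetas_deg: Sequence[float]) -> float:
    """Angle of the sum of unit vectors at each cell's preferred phase.

    Use only cells whose modulation is significant and unimodal.  NaN for
    an empty input.
    """
    thetas = np.asarray(thetas_deg, dtype=float)
    if thetas.size == 0:
        return float("nan")
    theta, _ = _resultant(np.radians(thetas))
    return theta
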
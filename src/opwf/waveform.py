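"""Cardiac-cycle synchronization and pulse-waveform (PWF) parameter extraction.

A region-mean MBR time series is collapsed onto one normalized cardiac cycle
(:func:`synchronize_cycles`) from which the full PWF parameter set is derived:
amplitude quantities (MBR/DC, MBRmax, MBRmin, AC), the blowout score and
blowout time, rising/falling area-ratio rates, the flow acceleration index,
the acceleration time index, the resistive index, and the S1/S2 limb areas
obtained through a second-order polynomial fit.

Conventions
-----------
* The cycle onset is the waveform minimum; ``t[i] = i * F / N``.
* Integrals run against the ``y = 0`` baseline (no offset subtraction).
* The rising phase is ``[0, t_peak]``, the falling phase ``[t_peak, F]``,
  with the cycle wrapping back to ``samples[0]`` at ``t = F``.
* Ties at the half-amplitude level count as "above"; plateau maxima use the
  first peak sample.
* A flat wave has blowout time 100 by convention (the half level equals the
  signal everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import (
    DegeneratePhaseError,
    DomainError,
    SynchronizationError,
    UnderdeterminedFitError,
)

__all__ = [
    "CardiacCycleWaveform",
    "Extrema",
    "WaveformAreas",
    "QuadraticFit",
    "PWFParameters",
    "synchronize_cycles",
    "waveform_extrema",
    "blowout_score",
    "blowout_time",
    "subdivide_waveform",
    "rising_rate",
    "falling_rate",
    "flow_acceleration_index",
    "acceleration_time_index",
    "resistivity_index",
    "fit_quadratic",
    "s1_area",
    "s2_area",
    "compute_pwf",
]

RATE_CONSTANT = 25.0  # color-balance constant C of the rate equations


@dataclass(frozen=True)
class CardiacCycleWaveform:
    """One normalized cardiac cycle of region-mean MBR.

    Parameters
    ----------
    samples
        ``N`` MBR values (arbitrary units) at times ``i * f / N``.
    f
        Cycle duration in seconds (full width of the wave).
    """

    samples: np.ndarray
    f: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        # scalar operations are defined for any N >= 2; the synchronizer
        # enforces its own N >= 8 output contract
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("cycle needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("cycle samples must be finite")
        if np.any(samples < 0):
            raise ValueError("MBR samples must be non-negative")
        if not (np.isfinite(self.f) and self.f > 0):
            raise ValueError("cycle duration f must be positive and finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * (self.f / self.n)


@dataclass(frozen=True)
class Extrema:
    mbr_max: float
    mbr_min: float
    ac: float
    dc: float
    t_peak: float


@dataclass(frozen=True)
class WaveformAreas:
    """Aggregate areas of the waveform subdivision.

    ``s1_under``/``rise_above`` partition the rising-phase rectangle
    ``[0, t_peak] x [0, mbr_max]``; ``fall_under``/``fall_above`` partition
    the falling-phase rectangle ``[t_peak, f] x [0, mbr_max]``.
    """

    t_peak: float
    f: float
    mbr_max: float
    s1_under: float
    rise_above: float
    fall_under: float
    fall_above: float
    w: float


@dataclass(frozen=True)
class QuadraticFit:
    a: float
    b: float
    c: float
    rmse: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * t * t + self.b * t + self.c

    def integral(self, t0: float, t1: float) -> float:
        """Closed-form integral of ``a t^2 + b t + c`` over ``[t0, t1]``."""
        antideriv = lambda t: self.a * t**3 / 3.0 + self.b * t**2 / 2.0 + self.c * t
        return antideriv(t1) - antideriv(t0)


@dataclass(frozen=True)
class PWFParameters:
    """The derived pulse-waveform parameter set for one cycle."""

    mbr: float  # DC, the cycle-mean MBR
    mbr_max: float
    mbr_min: float
    ac: float
    bos: float
    bot: float
    rr: float
    fr: float
    fai: float
    ati: float
    ri: float
    s1_area: float
    s2_area: float
    w: float
    f: float
    n_frames: int

    def as_dict(self) -> dict:
        return {
            "mbr": self.mbr,
            "mbr_max": self.mbr_max,
            "mbr_min": self.mbr_min,
            "ac": self.ac,
            "bos": self.bos,
            "bot": self.bot,
            "rr": self.rr,
            "fr": self.fr,
            "fai": self.fai,
            "ati": self.ati,
            "ri": self.ri,
            "s1_area": self.s1_area,
            "s2_area": self.s2_area,
            "w": self.w,
            "f": self.f,
            "n_frames": self.n_frames,
        }


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def _dominant_period(series: np.ndarray) -> float:
    """Dominant period in frames via the first autocorrelation peak."""
    z = series - series.mean()
    n = z.size
    acf = np.correlate(z, z, mode="full")[n - 1 :]
    if acf[0] <= 0:
        raise SynchronizationError("series has zero variance")
    acf = acf / acf[0]
    peaks, props = find_peaks(acf, height=0.1)
    if peaks.size == 0:
        raise SynchronizationError("no periodicity detectable (need >= 2 cycles)")
    lag = int(peaks[0])
    if lag < 2 or lag > n // 2:
        raise SynchronizationError("detected period incompatible with series length")
    return float(lag)


def synchronize_cycles(
    series: Sequence[float],
    frame_rate_hz: float,
    n_out: int = 30,
    smooth_sigma: float = 1.0,
) -> CardiacCycleWaveform:
    """Collapse a multi-cycle MBR series onto one normalized cardiac cycle.

    Cycle onsets are local minima of the (lightly smoothed) series spaced by
    the dominant autocorrelation period.  Each complete onset-to-onset segment
    is linearly resampled to ``n_out`` samples; the output is the pointwise
    mean of the segments and ``F`` the mean segment duration.

    Raises
    ------
    SynchronizationError
        If the series is flat or spans fewer than two cycles.
    """
    y = np.asarray(series, dtype=float)
    if n_out < 8:
        raise ValueError("n_out must be >= 8")
    if y.ndim != 1 or y.size < 2 * n_out // 2:
        raise SynchronizationError("series too short")
    if not np.all(np.isfinite(y)):
        raise SynchronizationError("series contains non-finite values")
    if np.ptp(y) == 0:
        raise SynchronizationError("constant series has no cardiac cycle")

    smooth = gaussian_filter1d(y, smooth_sigma) if smooth_sigma > 0 else y
    period = _dominant_period(smooth)

    minima, _ = find_peaks(-smooth, distance=max(2, int(round(0.7 * period))))
    if minima.size < 2:
        raise SynchronizationError("fewer than two cycle onsets found")

    segments = []
    lengths = []
    for start, stop in zip(minima[:-1], minima[1:]):
        length = stop - start
        if not (0.5 * period <= length <= 1.6 * period):
            continue  # partial/merged segment, skip
        pos = start + (length * np.arange(n_out)) / n_out
        segments.append(np.interp(pos, np.arange(y.size), y))
        lengths.append(length)
    if not segments:
        raise SynchronizationError("no complete onset-to-onset segment found")

    mean_cycle = np.maximum(np.mean(segments, axis=0), 0.0)
    f = float(np.mean(lengths)) / float(frame_rate_hz)
    return CardiacCycleWaveform(samples=mean_cycle, f=f)


# ---------------------------------------------------------------------------
# scalar parameters
# ---------------------------------------------------------------------------

def waveform_extrema(cycle: CardiacCycleWaveform) -> Extrema:
    """Max/min/mean of the cycle; ``t_peak`` is the time of the first maximum."""
    samples = cycle.samples
    i_peak = int(np.argmax(samples))
    return Extrema(
        mbr_max=float(samples.max()),
        mbr_min=float(samples.min()),
        ac=float(samples.max() - samples.min()),
        dc=float(samples.mean()),
        t_peak=i_peak * cycle.f / cycle.n,
    )


def blowout_score(ex: Extrema) -> float:
    """BOS = (2 - AC/DC) x 100, the vessel-resistance index."""
    if ex.dc <= 0:
        raise DomainError("blowout score undefined for DC <= 0")
    return (2.0 - ex.ac / ex.dc) * 100.0


def _piecewise_points(cycle: CardiacCycleWaveform) -> tuple[np.ndarray, np.ndarray]:
    """Sample grid extended with the wrap point (t = F, y = samples[0])."""
    t = np.append(cycle.times, cycle.f)
    y = np.append(cycle.samples, cycle.samples[0])
    return t, y


def blowout_time(cycle: CardiacCycleWaveform, ex: Extrema) -> tuple[float, float]:
    """Half width ``W`` and BOT = 100 x W/F.

    ``W`` is the total time the piecewise-linear waveform sits at or above
    the half level ``mbr_min + ac/2``, with crossings located by linear
    interpolation.  A flat wave returns ``(F, 100.0)`` by convention.
    """
    if ex.ac == 0:
        return cycle.f, 100.0
    half = ex.mbr_min + ex.ac / 2.0
    t, y = _piecewise_points(cycle)
    w = 0.0
    for t0, t1, y0, y1 in zip(t[:-1], t[1:], y[:-1], y[1:]):
        above0, above1 = y0 >= half, y1 >= half
        if above0 and above1:
            w += t1 - t0
        elif above0 != above1:
            tc = t0 + (half - y0) / (y1 - y0) * (t1 - t0)
            w += (tc - t0) if above0 else (t1 - tc)
    return w, 100.0 * w / cycle.f


def subdivide_waveform(cycle: CardiacCycleWaveform, ex: Extrema) -> WaveformAreas:
    """Split the cycle at the peak and integrate both limbs (trapezoid rule).

    Raises
    ------
    DegeneratePhaseError
        If the peak sits on the cycle boundary (e.g. a constant cycle), in
        which case the rising/falling subdivision is undefined.
    """
    i_peak = int(np.argmax(cycle.samples))
    if i_peak == 0:
        raise DegeneratePhaseError(
            "waveform subdivision degenerate: peak at cycle onset (t_peak = 0)"
        )
    t, y = _piecewise_points(cycle)
    t_peak = t[i_peak]
    s1_under = float(np.trapezoid(y[: i_peak + 1], t[: i_peak + 1]))
    fall_under = float(np.trapezoid(y[i_peak:], t[i_peak:]))
    rise_above = max(t_peak * ex.mbr_max - s1_under, 0.0)
    fall_above = max((cycle.f - t_peak) * ex.mbr_max - fall_under, 0.0)
    w, _ = blowout_time(cycle, ex)
    return WaveformAreas(
        t_peak=float(t_peak),
        f=cycle.f,
        mbr_max=ex.mbr_max,
        s1_under=s1_under,
        rise_above=rise_above,
        fall_under=fall_under,
        fall_above=fall_above,
        w=w,
    )


def rising_rate(areas: WaveformAreas) -> float:
    """RR = C x (under-curve rising area) / (its rectangle complement)."""
    if areas.rise_above <= 0:
        raise DegeneratePhaseError("rising rate undefined: instantaneous rise")
    return RATE_CONSTANT * areas.s1_under / areas.rise_above


def falling_rate(areas: WaveformAreas) -> float:
    """FR = C x (falling rectangle complement) / (under-curve falling area)."""
    if areas.fall_under <= 0:
        raise DomainError("falling rate undefined: zero under-curve falling area")
    return RATE_CONSTANT * areas.fall_above / areas.fall_under


def flow_acceleration_index(cycle: CardiacCycleWaveform) -> float:
    """FAI = max consecutive-frame MBR increment on the normalized cycle."""
    return float(np.max(np.diff(cycle.samples)))


def acceleration_time_index(cycle: CardiacCycleWaveform, ex: Extrema) -> float:
    """ATI = 100 x time-to-peak / F (conventional acceleration-time form)."""
    return 100.0 * ex.t_peak / cycle.f


def resistivity_index(ex: Extrema) -> float:
    """RI = (MBRmax - MBRmin) / MBRmax = AC / MBRmax."""
    if ex.mbr_max <= 0:
        raise DomainError("resistive index undefined for MBRmax <= 0")
    return ex.ac / ex.mbr_max


# ---------------------------------------------------------------------------
# quadratic-fit areas
# ---------------------------------------------------------------------------

def fit_quadratic(t: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """Least-squares second-order trend line ``y = a t^2 + b t + c``."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(t).size < 3:
        raise UnderdeterminedFitError("quadratic fit needs >= 3 distinct time points")
    design = np.column_stack([t * t, t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return QuadraticFit(a=float(coef[0]), b=float(coef[1]), c=float(coef[2]), rmse=rmse)


def _limb_points(cycle: CardiacCycleWaveform, rising: bool) -> tuple[np.ndarray, np.ndarray]:
    i_peak = int(np.argmax(cycle.samples))
    if i_peak == 0:
        raise DegeneratePhaseError("limb extraction degenerate: peak at cycle onset")
    t, y = _piecewise_points(cycle)
    if rising:
        return t[: i_peak + 1], y[: i_peak + 1]
    return t[i_peak:], y[i_peak:]


def s1_area(cycle: CardiacCycleWaveform, ex: Extrema) -> float:
    """S1 = integral of the fitted second-order trend over the rising limb."""
    t, y = _limb_points(cycle, rising=True)
    fit = fit_quadratic(t, y)
    return fit.integral(float(t[0]), float(t[-1]))


def s2_area(cycle: CardiacCycleWaveform, ex: Extrema, fr: float) -> float:
    """S2 = (fit integral over the falling limb) x FR / C."""
    t, y = _limb_points(cycle, rising=False)
    fit = fit_quadratic(t, y)
    return fit.integral(float(t[0]), float(t[-1])) * fr / RATE_CONSTANT


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

def compute_pwf(cycle: CardiacCycleWaveform) -> PWFParameters:
    """Compute every PWF parameter for one normalized cycle.

    Sub-operation errors propagate unchanged; their messages name the
    degenerate parameter (e.g. the subdivision for a constant cycle).
    """
    ex = waveform_extrema(cycle)
    areas = subdivide_waveform(cycle, ex)
    w, bot = areas.w, 100.0 * areas.w / cycle.f
    fr = falling_rate(areas)
    return PWFParameters(
        mbr=ex.dc,
        mbr_max=ex.mbr_max,
        mbr_min=ex.mbr_min,
        ac=ex.ac,
        bos=blowout_score(ex),
        bot=bot,
        rr=rising_rate(areas),
        fr=fr,
        fai=flow_acceleration_index(cycle),
        ati=acceleration_time_index(cycle, ex),
        ri=resistivity_index(ex),
        s1_area=s1_area(cycle, ex),
        s2_area=s2_area(cycle, ex, fr),
        w=w,
        f=cycle.f,
        n_frames=cycle.n,
    )
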
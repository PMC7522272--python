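"""Seeded synthetic LSFG acquisitions and longitudinal studies.

Everything downstream is testable against the ground truth generated here:
single-cycle pulse templates with closed-form parameter values, pixel-level
MBR frame stacks with known vessel/tissue masks, and full longitudinal
studies with a vessel-resistance (VRP) drift regime followed by a
vessel-elasticity (VEP) regime plus coupled NBA score trajectories.

MBR values are generated directly in arbitrary units; no speckle statistics
are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .errors import DomainError, InvalidConfigError, InvalidSpecError
from .segmentation import MBRFrameSequence, RegionMasks

__all__ = [
    "PulseTemplateSpec",
    "StudyConfig",
    "LongitudinalDataset",
    "PWF_PARAMS",
    "make_pulse_template",
    "evaluate_template",
    "triangular_closed_form",
    "simulate_frame_sequence",
    "simulate_longitudinal_study",
    "percent_stenosis",
    "DEFAULT_REGION_TEMPLATES",
    "DEFAULT_VRP_DRIFT",
    "DEFAULT_VEP_DRIFT",
]

SHAPES = ("triangular", "gamma_like")

#: the parameter columns carried by a longitudinal dataset
PWF_PARAMS = (
    "mbr",
    "mbr_max",
    "mbr_min",
    "ac",
    "bos",
    "bot",
    "rr",
    "fr",
    "fai",
    "ati",
    "ri",
    "s1_area",
    "s2_area",
    "w",
)


@dataclass(frozen=True)
class PulseTemplateSpec:
    """Single-cycle pulse template: DC level, AC amplitude, rise timing, shape."""

    dc: float
    ac: float
    rise_fraction: float
    shape: str = "triangular"
    n_frames: int = 30

    def __post_init__(self) -> None:
        if not isinstance(self.n_frames, (int, np.integer)) or self.n_frames <= 0:
            raise InvalidSpecError("n_frames must be a positive integer")
        if self.ac < 0:
            raise InvalidSpecError("ac must be non-negative")
        if self.dc <= self.ac / 2.0:
            raise InvalidSpecError("dc must exceed ac/2 so the waveform stays positive")
        if not 0.0 < self.rise_fraction < 1.0:
            raise InvalidSpecError("rise_fraction must lie in (0, 1)")
        if self.shape not in SHAPES:
            raise InvalidSpecError(f"shape must be one of {SHAPES}")


def _unit_shape(shape: str, rise_fraction: float, phases: np.ndarray) -> np.ndarray:
    """Raw pulse shape on cycle phases in [0, 1): min near 0, peak 1 at the rise end."""
    p = np.asarray(phases, dtype=float) % 1.0
    rf = rise_fraction
    if shape == "triangular":
        return np.where(p <= rf, p / rf, (1.0 - p) / (1.0 - rf))
    # gamma_like: gamma-density style rise, exponential fall
    a = 3.0
    tau = (1.0 - rf) / 3.0
    rise = (p / rf) ** a * np.exp(a * (1.0 - p / rf))
    fall = np.exp(-(p - rf) / tau)
    return np.where(p <= rf, rise, fall)


def make_pulse_template(spec: PulseTemplateSpec) -> np.ndarray:
    """Sample one cycle of the template at ``n_frames`` evenly spaced phases.

    The emitted samples are rescaled so that min = ``dc - ac/2`` and
    max = ``dc + ac/2`` exactly; for the triangular shape the sample mean
    equals ``dc`` in the continuous limit.
    """
    if spec.ac == 0:
        return np.full(spec.n_frames, float(spec.dc))
    phases = np.arange(spec.n_frames) / spec.n_frames
    u = _unit_shape(spec.shape, spec.rise_fraction, phases)
    u = (u - u.min()) / (u.max() - u.min())
    return spec.dc - spec.ac / 2.0 + spec.ac * u


def evaluate_template(spec: PulseTemplateSpec, phases: np.ndarray) -> np.ndarray:
    """Evaluate the template at arbitrary cycle phases.

    Uses periodic linear interpolation of the ``n_frames`` template samples,
    so pixel time series and the discrete template agree on the sample grid.
    """
    samples = make_pulse_template(spec)
    xp = np.arange(spec.n_frames + 1) / spec.n_frames
    fp = np.append(samples, samples[0])
    return np.interp(np.asarray(phases, dtype=float) % 1.0, xp, fp)


def triangular_closed_form(
    spec: PulseTemplateSpec, f: float, n_cycle: Optional[int] = None
) -> dict[str, float]:
    """Closed-form PWF parameter values for a triangular template.

    ``f`` is the cycle duration in seconds and ``n_cycle`` the normalized
    cycle frame count used for the (frame-unit) flow acceleration index.
    Used as the independent oracle for the waveform stage and as the
    ground-truth baseline of the longitudinal simulator.
    """
    if spec.shape != "triangular":
        raise InvalidSpecError("closed forms are available for the triangular shape")
    if spec.ac <= 0:
        raise InvalidSpecError("closed forms require ac > 0")
    n = n_cycle if n_cycle is not None else spec.n_frames
    dc, ac, p = spec.dc, spec.ac, spec.rise_fraction
    mbr_max = dc + ac / 2.0
    return {
        "mbr": dc,
        "mbr_max": mbr_max,
        "mbr_min": dc - ac / 2.0,
        "ac": ac,
        "bos": (2.0 - ac / dc) * 100.0,
        "bot": 50.0,
        "rr": 50.0 * dc / ac,
        "fr": 12.5 * ac / dc,
        "fai": ac / (p * n),
        "ati": 100.0 * p,
        "ri": ac / mbr_max,
        "s1_area": dc * p * f,
        "s2_area": (1.0 - p) * f * ac / 2.0,
        "w": f / 2.0,
    }


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

# relative per-day drift of each parameter in each regime
DEFAULT_VRP_DRIFT: dict[str, float] = {
    "bos": +0.010,
    "fai": -0.018,
    "ri": -0.018,
    "ac": -0.015,
    "mbr": +0.004,
    "mbr_max": +0.004,
    "mbr_min": +0.006,
}
DEFAULT_VEP_DRIFT: dict[str, float] = {
    "bos": -0.012,
    "bot": -0.010,
    "fr": -0.015,
    "fai": -0.018,
    "ri": -0.018,
    "ac": -0.015,
}

# vessels are bright in MBR composite maps: MV > MA > MT DC levels
DEFAULT_REGION_TEMPLATES: dict[str, PulseTemplateSpec] = {
    "MV": PulseTemplateSpec(dc=45.0, ac=12.0, rise_fraction=0.35, n_frames=256),
    "MT": PulseTemplateSpec(dc=25.0, ac=6.0, rise_fraction=0.35, n_frames=256),
    "MA": PulseTemplateSpec(dc=30.0, ac=7.5, rise_fraction=0.35, n_frames=256),
}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a synthetic longitudinal study."""

    n_rabbits: int = 6
    heart_rate_bpm: float = 240.0
    frame_rate_hz: float = 30.0
    acquisition_s: float = 4.0
    baseline_sessions: int = 8
    days: tuple[int, ...] = tuple(range(1, 29))
    vrp_end_day: int = 19
    vrp_drift: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VRP_DRIFT))
    vep_drift: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VEP_DRIFT))
    noise_sd: float = 0.5
    param_noise_scale: float = 0.06
    nba_effect_size: float = 1.0
    nba_slope: float = 0.35
    n_frames_cycle: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rabbits < 1 or self.baseline_sessions < 1:
            raise InvalidConfigError("need at least one rabbit and baseline session")
        if len(self.days) == 0:
            raise InvalidConfigError("days list must be non-empty")
        if any(d < 1 for d in self.days):
            raise InvalidConfigError("post-surgery days must be >= 1")
        if self.heart_rate_bpm <= 0 or self.frame_rate_hz <= 0 or self.acquisition_s <= 0:
            raise InvalidConfigError("rates and acquisition time must be positive")
        # the acquisition must span at least two cardiac cycles
        if self.acquisition_s * self.heart_rate_bpm / 60.0 < 2.0:
            raise InvalidConfigError(
                "acquisition must cover >= 2 cardiac cycles at heart_rate_bpm"
            )
        for name, drift in (("vrp_drift", self.vrp_drift), ("vep_drift", self.vep_drift)):
            for key, value in drift.items():
                if key not in PWF_PARAMS:
                    raise InvalidConfigError(f"{name}: unknown parameter {key!r}")
                if not np.isfinite(value):
                    raise InvalidConfigError(f"{name}: non-finite magnitude for {key!r}")
        if self.noise_sd < 0 or self.param_noise_scale < 0:
            raise InvalidConfigError("noise magnitudes must be non-negative")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    @property
    def n_frames_total(self) -> int:
        return round(self.frame_rate_hz * self.acquisition_s)


@dataclass(frozen=True)
class LongitudinalDataset:
    """Per-rabbit, per-day, per-region PWF values + NBA, with ground truth.

    ``data`` columns: rabbit_id, day, session, is_baseline, region,
    nba_total and one column per entry of :data:`PWF_PARAMS`.
    ``ground_truth`` holds the noise-free expected values and regime labels.
    """

    data: pd.DataFrame
    ground_truth: pd.DataFrame
    config: StudyConfig


# ---------------------------------------------------------------------------
# frame-level simulation
# ---------------------------------------------------------------------------

def _branching_vessel_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Procedural branching-line vessel pattern covering ~10-30% of the ROI."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    jitter = max(1, w // 8)
    col_top = int(np.clip(w // 2 + rng.integers(-jitter, jitter + 1), 0, w - 1))
    col_bot = int(np.clip(col_top + rng.integers(-jitter, jitter + 1), 0, w - 1))
    trunk_r, trunk_c = draw_line(0, col_top, h - 1, col_bot)
    mask[trunk_r, trunk_c] = True
    for k, frac in enumerate(np.linspace(0.15, 0.85, 4)):
        i = int(frac * (trunk_r.size - 1))
        r0, c0 = int(trunk_r[i]), int(trunk_c[i])
        dr = int(rng.integers(h // 4, max(h // 2, h // 4 + 1)))
        dcol = int(rng.integers(w // 4, max(w // 2, w // 4 + 1)))
        if k % 2:
            dcol = -dcol
        r1 = int(np.clip(r0 + dr, 0, h - 1))
        c1 = int(np.clip(c0 + dcol, 0, w - 1))
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    while mask.mean() < 0.10:
        mask = dilation(mask, disk(1))
    return mask


def simulate_frame_sequence(
    config: StudyConfig,
    template_vessel: PulseTemplateSpec,
    template_tissue: PulseTemplateSpec,
    seed: Optional[int] = None,
    shape: tuple[int, int] = (64, 64),
) -> tuple[MBRFrameSequence, RegionMasks]:
    """Simulate an ROI-sized MBR frame stack with known compartment masks.

    Every pixel's time series is its compartment template repeated at the
    configured heart rate, sampled at the frame rate, plus i.i.d. Gaussian
    noise of standard deviation ``config.noise_sd``.
    """
    if template_vessel.dc <= template_tissue.dc:
        raise InvalidSpecError("vessel template DC must exceed tissue template DC")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    mask = _branching_vessel_mask(shape, rng)
    times = np.arange(config.n_frames_total) / config.frame_rate_hz
    phases = times / config.cycle_s
    vessel_series = evaluate_template(template_vessel, phases)
    tissue_series = evaluate_template(template_tissue, phases)

    base = np.where(mask[None, :, :], vessel_series[:, None, None], tissue_series[:, None, None])
    if config.noise_sd > 0:
        base = base + rng.normal(0.0, config.noise_sd, size=base.shape)
    frames = np.maximum(base, 0.0)

    seq = MBRFrameSequence(
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
        acquisition_s=config.acquisition_s,
    )
    return seq, RegionMasks(vessel=mask, tissue=~mask)


# ---------------------------------------------------------------------------
# longitudinal simulation
# ---------------------------------------------------------------------------

def _expected_value(base: float, param: str, day: int, config: StudyConfig) -> float:
    """Noise-free expected parameter value on a given post-surgery day."""
    if day <= 0:
        return base
    vrp_days = min(day, config.vrp_end_day)
    vep_days = max(0, day - config.vrp_end_day)
    factor = (
        1.0
        + config.vrp_drift.get(param, 0.0) * vrp_days
        + config.vep_drift.get(param, 0.0) * vep_days
    )
    return base * factor


def _nba_total(day: int, is_baseline: bool, config: StudyConfig, rng: np.random.Generator) -> int:
    if is_baseline:
        raw = rng.normal(0.0, 0.4)
    else:
        noise_sd = 1.5 / max(config.nba_effect_size, 1e-9)
        raw = config.nba_slope * day + rng.normal(0.0, noise_sd)
    return int(np.clip(round(raw), 0, 19))


def simulate_longitudinal_study(
    config: StudyConfig,
    region_templates: Optional[Mapping[str, PulseTemplateSpec]] = None,
) -> LongitudinalDataset:
    """Simulate a full longitudinal study at the PWF-parameter level.

    Baseline parameter values are the closed-form values of each region's
    triangular template.  Post-surgery values drift multiplicatively:
    through ``vrp_end_day`` under ``vrp_drift`` (BOS up; FAI, RI, AC down;
    BOT, FR flat) and afterwards additionally under ``vep_drift`` (all six
    down).  Observed values carry relative Gaussian noise of
    ``noise_sd * param_noise_scale``; NBA totals follow an affine ramp in
    the day index with discrete noise, clamped to [0, 19].
    """
    templates = dict(region_templates or DEFAULT_REGION_TEMPLATES)
    missing = {"MA", "MV", "MT"} - set(templates)
    if missing:
        raise InvalidConfigError(f"region templates missing {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    rel_sd = config.noise_sd * config.param_noise_scale
    f = config.cycle_s
    base_params = {
        region: triangular_closed_form(spec, f, n_cycle=config.n_frames_cycle)
        for region, spec in templates.items()
    }

    sessions: list[tuple[int, int, bool]] = [
        (0, s + 1, True) for s in range(config.baseline_sessions)
    ] + [(int(day), 1, False) for day in config.days]

    rows = []
    truth_rows = []
    for r in range(config.n_rabbits):
        rabbit = f"R{r + 1:02d}"
        for day, session, is_baseline in sessions:
            nba = _nba_total(day, is_baseline, config, rng)
            for region in ("MA", "MV", "MT"):
                base = base_params[region]
                expected = {
                    p: _expected_value(base[p], p, day, config) for p in PWF_PARAMS
                }
                noisy = {
                    p: expected[p] * (1.0 + rng.normal(0.0, rel_sd)) if rel_sd > 0 else expected[p]
                    for p in PWF_PARAMS
                }
                regime = (
                    "baseline"
                    if is_baseline
                    else ("vrp" if day <= config.vrp_end_day else "vep")
                )
                rows.append(
                    {
                        "rabbit_id": rabbit,
                        "day": day,
                        "session": session,
                        "is_baseline": is_baseline,
                        "region": region,
                        "nba_total": nba,
                        **noisy,
                    }
                )
                truth_rows.append(
                    {
                        "rabbit_id": rabbit,
                        "day": day,
                        "session": session,
                        "is_baseline": is_baseline,
                        "region": region,
                        "regime": regime,
                        **expected,
                    }
                )

    data = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return LongitudinalDataset(data=data, ground_truth=truth, config=config)


def percent_stenosis(d_baseline: float, d_residual: float) -> float:
    """Percent diameter stenosis: ``100 * (1 - d_residual / d_baseline)``."""
    if d_baseline <= 0:
        raise DomainError("baseline diameter must be positive")
    if d_residual < 0 or d_residual > d_baseline:
        raise DomainError("residual diameter must lie in [0, d_baseline]")
    return 100.0 * (1.0 - d_residual / d_baseline)
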
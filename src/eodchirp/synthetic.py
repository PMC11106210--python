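"""Synthetic EOD recordings with schedulable chirps and exact annotations.

Wave-type electric fish hold their discharge frequency remarkably steady
(coefficient of variation below 0.2% over half an hour), so a realistic
surrogate is a phase-continuous quasi-sinusoid in the 650--1000 Hz range
with slow frequency jitter and amplitude drift, onto which transient
chirp events are superimposed: brief (tens of ms) frequency excursions of
~100--400 Hz with an optional undershoot, accompanied by amplitude drops
between a few percent and ~50%.

The frequency pulse of a chirp reuses the sech-shaped template of the
TFSB baseline; a type-1-style undershoot is modeled as a delayed
negative lobe.  Every scheduled event yields an exact ground-truth
annotation spanning three durations on either side of the event center,
mirroring the instruction to annotators to include pre- and post-chirp
baseline points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .gt_processing import ChirpAnnotation
from .signal_extraction import VoltageTrace
from .tfsb import waveform

#: FWHM of sech(alpha*T) is 2*arccosh(2)/alpha; we set FWHM = duration/2
_SECH_FWHM = 2.0 * float(np.arccosh(2.0))


@dataclass(frozen=True)
class ChirpTypeSpec:
    """Parameterization of one chirp type.

    Δf_max (``df_max``) is the peak frequency rise in Hz; ``undershoot_frac``
    the area fraction of the delayed negative frequency lobe;
    ``amp_drop`` the fractional amplitude reduction at the peak;
    ``duration`` the event duration in seconds; ``n_peaks`` 1 for the
    classic short types, 2 for the double-peaked shape.
    """

    name: str
    df_max: float
    undershoot_frac: float
    amp_drop: float
    duration: float
    n_peaks: int = 1

    def __post_init__(self) -> None:
        if self.df_max <= 0 or self.duration <= 0:
            raise ValueError("df_max and duration must be positive")
        if not 0 <= self.amp_drop < 1:
            raise ValueError("amp_drop must be in [0, 1)")
        if self.n_peaks not in (1, 2):
            raise ValueError("n_peaks must be 1 or 2")


def preset_types() -> dict[str, ChirpTypeSpec]:
    """The three built-in chirp types.

    type1: large rise (~400 Hz) with undershoot and ~50% amplitude drop;
    type2: small rise (~100 Hz), no undershoot, <10% amplitude drop;
    novel2peak: the short double-peaked shape with paired amplitude drops.
    """
    return {
        "type1": ChirpTypeSpec("type1", 400.0, 0.1, 0.5, 0.020, 1),
        "type2": ChirpTypeSpec("type2", 100.0, 0.0, 0.08, 0.020, 1),
        "novel2peak": ChirpTypeSpec("novel2peak", 100.0, 0.0, 0.3, 0.025, 2),
    }


def alpha_for_duration(duration: float) -> float:
    """Sech-pulse steepness whose full width at half maximum is duration/2."""
    return 2.0 * _SECH_FWHM / duration


def chirp_profile(
    spec: ChirpTypeSpec, t_rel: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency excursion (Hz) and amplitude factor at times relative to
    the event center.

    Single peak: Δf(t) = df_max * [w(t) - undershoot_frac * w(t - 0.7*dur)]
    where w is the sech pulse; the subtracted lobe carries an area fraction
    ``undershoot_frac`` of the main lobe.  Two peaks: two narrower pulses
    at ±duration/4, scaled so the profile maximum equals df_max.  The
    amplitude factor dips by ``amp_drop`` with the same pulse shape.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    if spec.n_peaks == 1:
        alpha = alpha_for_duration(spec.duration)
        shape = waveform(t_rel, alpha)
        if spec.undershoot_frac > 0:
            shape = shape - spec.undershoot_frac * waveform(
                t_rel - 0.7 * spec.duration, alpha
            )
        df = spec.df_max * shape
        amp = 1.0 - spec.amp_drop * waveform(t_rel, alpha)
    else:
        alpha = alpha_for_duration(spec.duration / 2.0)
        off = spec.duration / 4.0
        raw = waveform(t_rel - off, alpha) + waveform(t_rel + off, alpha)
        peak = 1.0 + waveform(2.0 * off, alpha)  # value at either sub-peak
        df = spec.df_max * raw / peak
        amp = 1.0 - spec.amp_drop * raw / peak
    return df, amp


@dataclass
class ChirpSchedule:
    """A trace recipe: carrier, noise levels, and scheduled chirp events."""

    duration: float                       # s
    f0: float = 750.0                     # Hz, carrier baseline
    amplitude: float = 1.0
    fs: float = 20000.0                   # Hz, sampling rate
    events: list[tuple[float, ChirpTypeSpec]] = field(default_factory=list)
    freq_jitter_sd: float = 0.5           # Hz, slow carrier wander
    amp_drift_sd: float = 0.01            # relative, slow amplitude drift
    seed: int = 0

    def __post_init__(self) -> None:
        for t, spec in self.events:
            if not 0 <= t <= self.duration:
                raise ValueError(f"event at {t}s outside trace of {self.duration}s")

    def annotations(self, recording_id: str = "synthetic") -> list[ChirpAnnotation]:
        return [
            ChirpAnnotation(recording_id, t - 3 * spec.duration, t + 3 * spec.duration)
            for t, spec in sorted(self.events)
        ]


def regular_schedule(
    duration: float,
    n_events: int,
    spec: ChirpTypeSpec,
    seed: int = 0,
    margin: float = 2.0,
    **kwargs,
) -> ChirpSchedule:
    """Events evenly spread over the trace with seeded timing dither."""
    rng = np.random.default_rng(seed)
    slot = (duration - 2 * margin) / n_events
    centers = margin + slot * (np.arange(n_events) + 0.5)
    centers = centers + rng.uniform(-0.2, 0.2, n_events) * min(slot / 3, 1.0)
    return ChirpSchedule(
        duration=duration,
        events=[(float(t), spec) for t in centers],
        seed=seed,
        **kwargs,
    )


def _slow_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying Gaussian process with the requested marginal sd.

    White noise on a 10 Hz grid, Gaussian-smoothed, interpolated to the
    sample grid, and rescaled; emulates carrier wander / electrode drift.
    """
    if sd <= 0:
        return np.zeros(n)
    coarse_rate = 10.0
    n_coarse = max(int(np.ceil(n / fs * coarse_rate)) + 2, 4)
    coarse = gaussian_filter1d(rng.standard_normal(n_coarse), sigma=2.0)
    x = np.interp(
        np.arange(n) / fs, np.arange(n_coarse) / coarse_rate, coarse
    )
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def synthesize(
    schedule: ChirpSchedule, recording_id: str = "synthetic"
) -> tuple[VoltageTrace, list[ChirpAnnotation]]:
    """Render a schedule into a phase-continuous voltage trace.

    v(t) = A(t) sin(2π ∫ f dt) with f(t) the baseline plus jitter plus all
    chirp frequency excursions, and A(t) the baseline amplitude times
    drift times all chirp amplitude factors.  Overlapping annotations are
    rejected: detector evaluation assumes one chirp per interval.
    """
    anns = schedule.annotations(recording_id)
    for a, b in zip(anns, anns[1:]):
        if b.t_start <= a.t_end:
            raise ValueError(
                f"overlapping events near {a.t_end:.3f}s; space them out"
            )
    rng = np.random.default_rng(schedule.seed)
    n = int(round(schedule.duration * schedule.fs))
    t = np.arange(n) / schedule.fs

    f = np.full(n, schedule.f0) + _slow_noise(n, schedule.fs, schedule.freq_jitter_sd, rng)
    amp = schedule.amplitude * (
        1.0 + _slow_noise(n, schedule.fs, schedule.amp_drift_sd, rng)
    )
    for t_c, spec in schedule.events:
        # chirp support: profile is negligible beyond ±4 durations
        lo = max(int((t_c - 4 * spec.duration) * schedule.fs), 0)
        hi = min(int((t_c + 4 * spec.duration) * schedule.fs) + 1, n)
        df, af = chirp_profile(spec, t[lo:hi] - t_c)
        f[lo:hi] += df
        amp[lo:hi] *= af

    phase = 2.0 * np.pi * np.cumsum(f) / schedule.fs
    v = amp * np.sin(phase)
    return VoltageTrace(t0=0.0, fs=schedule.fs, v=v), anns
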
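"""Oscillation-level feature extraction from raw EOD voltage recordings.

Wave-type electric fish emit a quasi-sinusoidal electric organ discharge
(EOD) in the 650--1000 Hz range.  Every analysis step downstream operates
not on raw voltage but on a per-oscillation series ``(T_k, f_k, A_k)``:
for each EOD period *k*, the time of its upward zero crossing, the
reciprocal of the period, and the half peak-to-peak amplitude.

The extraction runs in short overlapping windows: per window the carrier
fundamental is located on the power spectrum, the voltage is band-passed
around it with a zero-phase filter (so crossing times are not skewed),
and upward zero crossings are found with linear sub-sample interpolation.
Windows are stitched so each oscillation is reported exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: default spectral search band for the EOD fundamental, Hz
DEFAULT_SEARCH_BAND = (500.0, 1200.0)

#: minimum ratio of spectral peak power to in-band median power for a
#: window to count as carrying a carrier (20 dB)
CARRIER_SNR_MIN = 100.0


class NoCarrierError(ValueError):
    """No spectral peak above the noise floor inside the search band."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VoltageTrace:
    """Uniformly sampled raw voltage.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    fs : float
        Sampling rate, Hz.
    v : ndarray
        Voltage samples, arbitrary units.
    """

    t0: float
    fs: float
    v: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.v.ndim != 1 or self.v.size < 2:
            raise ValueError("voltage trace needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.v.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.v.size) / self.fs

    @classmethod
    def from_wav(cls, path: str | Path, t0: float = 0.0) -> "VoltageTrace":
        fs, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / np.abs(np.iinfo(data.dtype).min)
        return cls(t0=t0, fs=float(fs), v=np.asarray(data, dtype=float))

    @classmethod
    def from_text(cls, path: str | Path) -> "VoltageTrace":
        """Read a two-column delimited file (time_s, voltage)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time column is not uniformly sampled")
        return cls(t0=float(t[0]), fs=1.0 / float(dt.mean()), v=v)


@dataclass
class OscillationSeries:
    """Per-oscillation (time, frequency, amplitude) triples.

    ``T`` holds each oscillation's upward-zero-crossing time (strictly
    increasing), ``f`` the reciprocal period in Hz, ``A`` the half
    peak-to-peak amplitude over the oscillation interval.
    """

    T: np.ndarray
    f: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if not (self.T.size == self.f.size == self.A.size):
            raise ValueError("T, f, A must have equal length")
        if self.T.size and np.any(np.diff(self.T) <= 0):
            raise ValueError("oscillation times must be strictly increasing")

    def __len__(self) -> int:
        return self.T.size

    def slice(self, mask: np.ndarray) -> "OscillationSeries":
        return OscillationSeries(self.T[mask], self.f[mask], self.A[mask])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"T_s": self.T, "f_Hz": self.f, "A": self.A}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "OscillationSeries":
        df = pd.read_csv(path)
        return cls(
            df["T_s"].to_numpy(float),
            df["f_Hz"].to_numpy(float),
            df["A"].to_numpy(float),
        )


@dataclass
class Segment:
    """A fixed-time-length slice of an OscillationSeries."""

    recording_id: str
    index: int
    t_lo: float
    t_hi: float
    points: OscillationSeries = field(repr=False)


# ---------------------------------------------------------------------------
# spectral carrier estimation
# ---------------------------------------------------------------------------

def estimate_fundamental(
    v: np.ndarray,
    fs: float,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
) -> float:
    """Locate the EOD fundamental on the power spectrum.

    Returns the frequency of the highest-power spectral peak inside
    ``search_band``, refined below bin resolution by quadratic
    interpolation of the log-power around the peak.

    Raises
    ------
    NoCarrierError
        If no in-band peak rises above the noise floor (peak power less
        than ``CARRIER_SNR_MIN`` times the in-band median power).
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    spec = np.fft.rfft(v - v.mean())
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    lo, hi = search_band
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise NoCarrierError(f"search band {search_band} outside spectrum")
    band_power = power[band]
    peak_rel = int(np.argmax(band_power))
    peak = np.flatnonzero(band)[peak_rel]
    floor = np.median(band_power)
    if power[peak] <= 0 or (floor > 0 and power[peak] < CARRIER_SNR_MIN * floor):
        raise NoCarrierError(
            f"no spectral peak above noise floor in {search_band} Hz"
        )
    if floor == 0 and power[peak] == 0:
        raise NoCarrierError("empty spectrum")

    # quadratic (parabolic) refinement on log power
    if 0 < peak < power.size - 1 and power[peak - 1] > 0 and power[peak + 1] > 0:
        lp = np.log(power[peak - 1 : peak + 2])
        denom = lp[0] - 2 * lp[1] + lp[2]
        delta = 0.5 * (lp[0] - lp[2]) / denom if denom < 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float((peak + delta) * fs / n)


def bandpass_window(
    v: np.ndarray, fs: float, f0: float, order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass around the fundamental, passband [0.5, 1.5]*f0.

    Forward-backward (filtfilt) filtering keeps zero crossings in place,
    which is what makes the crossing-time estimates unbiased.
    """
    if not 0 < f0 < fs / 3:
        raise ValueError(f"f0={f0} outside (0, fs/3) for fs={fs}")
    sos = sps.butter(order, [0.5 * f0, 1.5 * f0], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(v, dtype=float))


#: sinusoid-extension padding length for window filtering, carrier periods
_PAD_PERIODS = 40
#: edge samples used to fit the extension sinusoid, carrier periods
_FIT_PERIODS = 4


def _sine_extension(v: np.ndarray, fs: float, f0: float,
                    side: str) -> np.ndarray:
    """Continue the carrier beyond one edge of a window.

    A sinusoid at the known fundamental is least-squares fitted to the
    outermost few periods and evaluated past the edge.  Padding with this
    continuation (instead of filtfilt's reflected signal) removes the
    filter's edge transient for a locally sinusoidal carrier, keeping
    crossing estimates clean right up to the window boundary.
    """
    npad = int(round(_PAD_PERIODS * fs / f0))
    nfit = max(int(round(_FIT_PERIODS * fs / f0)), 4)
    w = 2 * np.pi * f0 / fs
    if side == "left":
        i = np.arange(nfit)
        seg = v[:nfit]
        i_out = np.arange(-npad, 0)
    else:
        i = np.arange(v.size - nfit, v.size)
        seg = v[-nfit:]
        i_out = np.arange(v.size, v.size + npad)
    design = np.column_stack([np.sin(w * i), np.cos(w * i)])
    coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
    return np.sin(w * i_out) * coef[0] + np.cos(w * i_out) * coef[1]


def _bandpass_padded(v: np.ndarray, fs: float, f0: float,
                     order: int) -> np.ndarray:
    """Band-pass a window between sinusoid extensions, then crop them off."""
    left = _sine_extension(v, fs, f0, "left")
    right = _sine_extension(v, fs, f0, "right")
    padded = np.concatenate([left, v, right])
    filt = bandpass_window(padded, fs, f0, order=order)
    return filt[left.size : left.size + v.size]


# ---------------------------------------------------------------------------
# zero-crossing oscillation series
# ---------------------------------------------------------------------------

def _upward_crossings(x: np.ndarray, t0: float, fs: float) -> np.ndarray:
    """Times of upward zero crossings with linear sub-sample interpolation."""
    idx = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0))
    if idx.size == 0:
        return np.empty(0)
    frac = -x[idx] / (x[idx + 1] - x[idx])
    return t0 + (idx + frac) / fs


def _window_oscillations(
    filt: np.ndarray, t0: float, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(T, f, A) triples for every full oscillation in one filtered window."""
    tc = _upward_crossings(filt, t0, fs)
    if tc.size < 2:
        return np.empty(0), np.empty(0), np.empty(0)
    periods = np.diff(tc)
    T = tc[:-1]
    f = 1.0 / periods
    # half peak-to-peak of the filtered voltage within each interval
    A = np.empty(T.size)
    start = np.clip(np.floor((tc - t0) * fs).astype(int), 0, filt.size - 1)
    for k in range(T.size):
        seg = filt[start[k] : max(start[k] + 2, start[k + 1] + 1)]
        A[k] = 0.5 * (seg.max() - seg.min())
    return T, f, A


def extract_oscillations(
    trace: VoltageTrace,
    window_s: float = 3.0,
    overlap_s: float = 2.0,
    search_band: tuple[float, float] = DEFAULT_SEARCH_BAND,
    filter_order: int = 4,
) -> OscillationSeries:
    """Extract the per-oscillation (T, f, A) series from a voltage trace.

    The trace is processed in ``window_s``-second windows advancing by
    ``window_s - overlap_s``; per window the fundamental is estimated,
    the signal band-passed, and upward crossings collected.  Each window
    only contributes crossings from its central advancing sub-interval
    (the first window also covers its leading edge, the last its trailing
    edge), so overlapping windows never report the same oscillation twice.

    Windows without a detectable carrier contribute nothing (gap, logged).
    """
    if trace.duration < window_s:
        raise ValueError(
            f"trace duration {trace.duration:.3f}s shorter than window {window_s}s"
        )
    advance = window_s - overlap_s
    if advance <= 0:
        raise ValueError("overlap must be smaller than the window")

    fs, v, t0 = trace.fs, trace.v, trace.t0
    nwin = int(round(window_s * fs))
    last_start_t = trace.duration - window_s
    starts = list(np.arange(0.0, last_start_t + 1e-9, advance))
    if not starts or last_start_t - starts[-1] > 1e-9:
        starts.append(last_start_t)

    lead = overlap_s / 2.0
    T_all, f_all, A_all = [], [], []
    for m, s in enumerate(starts):
        i0 = int(round(s * fs))
        win = v[i0 : i0 + nwin]
        w_t0 = t0 + i0 / fs
        try:
            f0 = estimate_fundamental(win, fs, search_band)
        except NoCarrierError:
            logger.warning("no carrier in window starting at %.3f s", w_t0)
            continue
        filt = _bandpass_padded(win, fs, f0, order=filter_order)
        T, f, A = _window_oscillations(filt, w_t0, fs)
        if T.size == 0:
            continue
        # responsibility interval of this window (absolute times)
        r_lo = -np.inf if m == 0 else t0 + s + lead
        r_hi = np.inf if m == len(starts) - 1 else t0 + s + lead + advance
        keep = (T >= r_lo) & (T < r_hi)
        T_all.append(T[keep])
        f_all.append(f[keep])
        A_all.append(A[keep])

    if not T_all:
        return OscillationSeries(np.empty(0), np.empty(0), np.empty(0))
    T = np.concatenate(T_all)
    f = np.concatenate(f_all)
    A = np.concatenate(A_all)
    order = np.argsort(T, kind="stable")
    T, f, A = T[order], f[order], A[order]
    # guard against numerically coincident crossings at stitch seams
    keep = np.concatenate([[True], np.diff(T) > 0])
    return OscillationSeries(T[keep], f[keep], A[keep])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_series(
    series: OscillationSeries,
    t_start: float,
    t_end: float,
    n_s: int,
    recording_id: str = "",
) -> list[Segment]:
    """Cut ``[t_start, t_end]`` into ``n_s`` equal-duration segments.

    Boundary points go to the half-open interval ``[lo, hi)`` except for
    the final segment, which is closed, so the segments partition every
    point in range.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    dT = (t_end - t_start) / n_s
    segments = []
    for j in range(1, n_s + 1):
        lo = t_start + (j - 1) * dT
        hi = t_start + j * dT
        if j < n_s:
            mask = (series.T >= lo) & (series.T < hi)
        else:
            mask = (series.T >= lo) & (series.T <= hi)
        if not mask.any():
            logger.warning("segment %d of %s is empty", j, recording_id or "?")
        segments.append(
            Segment(recording_id, j, lo, hi, series.slice(mask))
        )
    return segments
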
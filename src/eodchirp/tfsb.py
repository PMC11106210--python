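"""Time-frequency-shape-based (TFSB) reference detector.

Instead of learning waveforms from data, this baseline assumes that the
normalized frequency during a chirp follows the single-parameter pulse

    phi(T; alpha) = 2 exp(alpha T) / (1 + exp(2 alpha T)) = sech(alpha T),

peaked at 1, symmetric, with alpha (1/s) controlling the chirp's
duration.  Each sliding window is normalized like a training sample, the
template peak is aligned with the window's frequency maximum, and the
best coefficient of determination over a linear grid of alpha values is
thresholded, together with the window's frequency rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .chirp_detection import DetectionEvent, _consolidate
from .gt_processing import N_MED_DEFAULT
from .signal_extraction import OscillationSeries

TFSB_CHUNK = 1024  # windows per block (each expands by the alpha grid)


@dataclass
class TFSBParams:
    """Fixed and tunable TFSB hyperparameters.

    ``n_wind + 1`` is the window size in oscillations; the alpha grid is
    ``n_alpha`` linearly spaced values in [alpha_min, alpha_max] (1/s).
    ``eps_f`` (Hz) and ``eps_r2`` are the detection thresholds.
    """

    n_wind: int = 100
    n_med: int = N_MED_DEFAULT
    n_alpha: int = 200
    alpha_min: float = 100.0
    alpha_max: float = 800.0
    eps_f: float = 0.0
    eps_r2: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_min >= self.alpha_max:
            raise ValueError("alpha_min must be below alpha_max")
        if self.n_alpha < 2:
            raise ValueError("n_alpha must be >= 2")

    def alpha_grid(self) -> np.ndarray:
        return np.linspace(self.alpha_min, self.alpha_max, self.n_alpha)


def waveform(T: np.ndarray | float, alpha: float | np.ndarray) -> np.ndarray:
    """Chirp pulse phi(T; alpha) = sech(alpha T), evaluated overflow-safely."""
    x = np.abs(np.asarray(alpha) * np.asarray(T, dtype=float))
    e = np.exp(-x)
    return 2.0 * e / (1.0 + e * e)


def tfsb_scan(
    series: OscillationSeries, params: TFSBParams
) -> list[DetectionEvent]:
    """Scan a series with the assumed-waveform template.

    Events carry the best-grid R^2 as score; the ``cluster`` field holds
    the index of the best-matching alpha grid value.
    """
    L = params.n_wind + 1
    M = len(series)
    if M <= params.n_wind:
        return []
    Fw = sliding_window_view(series.f, L)
    Tw = sliding_window_view(series.T, L)
    n_windows = Fw.shape[0]
    alphas = params.alpha_grid()
    n_med = params.n_med

    # reusable (chunk, n_alpha, L) float32 scratch: the template stack is
    # by far the dominant cost, so it is built in-place in single precision
    buf = np.empty((TFSB_CHUNK, params.n_alpha, L), dtype=np.float32)
    tmp = np.empty_like(buf)
    alphas32 = alphas.astype(np.float32)

    hits_idx, hits_score, hits_alpha, hits_peak_t = [], [], [], []
    for start in range(0, n_windows, TFSB_CHUNK):
        stop = min(start + TFSB_CHUNK, n_windows)
        w = stop - start
        F = np.ascontiguousarray(Fw[start:stop])
        T = np.ascontiguousarray(Tw[start:stop])
        edges = np.concatenate([F[:, :n_med], F[:, -n_med:]], axis=1)
        f_base = np.median(edges, axis=1)
        rise = F.max(axis=1) - f_base
        valid = rise > 0
        safe_rise = np.where(valid, rise, 1.0)
        phi = (F - f_base[:, None]) / safe_rise[:, None]
        # center template on the window's frequency maximum; a peak inside
        # the edge region contradicts the assumption that the first/last
        # n_med points are baseline, so such windows cannot be aligned
        j_pk = np.argmax(phi, axis=1)
        valid &= (j_pk >= n_med) & (j_pk <= L - 1 - n_med)
        T_rel = np.abs(T - T[np.arange(w), j_pk][:, None]).astype(np.float32)
        # templates sech(alpha*|T_rel|) = 2 e / (1 + e^2), e = exp(-alpha*|T|)
        E = buf[:w]
        S = tmp[:w]
        np.multiply(T_rel[:, None, :], alphas32[None, :, None], out=E)
        np.negative(E, out=E)
        np.exp(E, out=E)                       # e
        np.multiply(E, E, out=S)               # e^2
        S += 1.0
        np.divide(E, S, out=E)
        E *= 2.0                               # waveform values
        np.subtract(phi[:, None, :].astype(np.float32), E, out=E)
        np.multiply(E, E, out=E)
        sse = E.sum(axis=2, dtype=np.float64)
        sst = np.sum((phi - phi.mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - sse / sst[:, None]
        r2[sst == 0] = -np.inf
        best_a = np.argmax(r2, axis=1)
        best_r2 = r2[np.arange(r2.shape[0]), best_a]
        hit = valid & (best_r2 > params.eps_r2) & (rise > params.eps_f)
        loc = np.flatnonzero(hit)
        hits_idx.append(loc + start)
        hits_score.append(best_r2[loc])
        hits_alpha.append(best_a[loc])
        # event time of a template match is its aligned peak time
        hits_peak_t.append(T[loc, j_pk[loc]])

    indices = np.concatenate(hits_idx)
    scores = np.concatenate(hits_score)
    grid_idx = np.concatenate(hits_alpha)
    peak_times = np.concatenate(hits_peak_t)
    return _consolidate(
        indices, scores, grid_idx, series.T, "tfsb", prefer_max=True,
        event_times=peak_times,
    )
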
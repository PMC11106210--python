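"""Sliding-window chirp detection against a trained waveform model.

A window of ``10**r + 1`` consecutive oscillations slides over the
(T, f, A) series one oscillation at a time.  Each window is normalized
exactly like a training sample (base values from its own edge points),
then scored either by

* MDB — project onto the retained principal components, pick the kept
  Gaussian cluster with the highest posterior, and threshold the squared
  Mahalanobis distance against a chi-squared quantile; or
* CDB — threshold the coefficient of determination of the window's
  frequency waveform against the best-matching kept cluster mean.

Both methods additionally require the window's maximum frequency rise
above its base frequency to exceed ``eps_f``.  Maximal runs of
consecutive accepted windows are consolidated into single events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .gt_processing import N_MED_DEFAULT
from .model_training import TrainedModel
from .signal_extraction import OscillationSeries

logger = logging.getLogger(__name__)

CHUNK = 16384  # windows scored per block; bounds peak memory


@dataclass
class DetectorConfig:
    """Thresholds for a sliding-window scan.

    eps_f is the minimum frequency rise (Hz); alpha the significance level
    setting the MDB chi-squared threshold; eps_r2 the CDB CoD threshold.
    """

    method: str = "cdb"              # "mdb" or "cdb"
    eps_f: float = 0.0
    alpha: float = 0.05
    eps_r2: float = 0.5
    n_med: int = N_MED_DEFAULT

    def __post_init__(self) -> None:
        if self.method not in ("mdb", "cdb"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.eps_r2 <= 1:
            raise ValueError("eps_r2 must be in [0, 1]")
        if self.eps_f < 0:
            raise ValueError("eps_f must be non-negative")


@dataclass
class DetectionEvent:
    """One consolidated chirp call."""

    time: float            # start time of the representative window
    window_index: int
    cluster: int
    score: float           # squared Mahalanobis distance (MDB) or R^2 (CDB)
    method: str
    run_first: int
    run_last: int


def chi2_threshold(alpha: float, N: int) -> float:
    """(1 - alpha) quantile of chi-squared with N degrees of freedom."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df=N))


# ---------------------------------------------------------------------------
# window normalization
# ---------------------------------------------------------------------------

def normalize_windows(
    F: np.ndarray, A: np.ndarray, n_med: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalize a block of windows the way training samples are normalized.

    Parameters
    ----------
    F, A : (w, L) arrays of per-window frequencies and amplitudes.

    Returns
    -------
    phi, a : (w, L) normalized windows (rows with rise <= 0 are zeroed)
    rise : (w,) maximum frequency rise above the window base, Hz
    valid : (w,) bool, False where rise <= 0 or base amplitude is 0
        (such windows cannot be normalized and are skipped by detectors)
    """
    edges_f = np.concatenate([F[:, :n_med], F[:, -n_med:]], axis=1)
    edges_a = np.concatenate([A[:, :n_med], A[:, -n_med:]], axis=1)
    f_base = np.median(edges_f, axis=1)
    a_base = np.median(edges_a, axis=1)
    rise = F.max(axis=1) - f_base
    valid = (rise > 0) & (a_base != 0)
    safe_rise = np.where(valid, rise, 1.0)
    safe_base = np.where(a_base != 0, a_base, 1.0)
    phi = (F - f_base[:, None]) / safe_rise[:, None]
    a = (A - a_base[:, None]) / safe_base[:, None]
    phi[~valid] = 0.0
    a[~valid] = 0.0
    return phi, a, rise, valid


def _consolidate(
    indices: np.ndarray,
    scores: np.ndarray,
    clusters: np.ndarray,
    times: np.ndarray,
    method: str,
    prefer_max: bool,
    event_times: np.ndarray | None = None,
) -> list[DetectionEvent]:
    """Merge maximal runs of consecutive window indices into events.

    The representative window is the run's best-scoring one (max R^2 for
    CDB, min d^2 for MDB); ties break toward the earliest window.  The
    event time is the representative window's start time unless
    ``event_times`` supplies a per-hit time (the TFSB template's matched
    peak time).
    """
    events: list[DetectionEvent] = []
    if indices.size == 0:
        return events
    breaks = np.flatnonzero(np.diff(indices) > 1) + 1
    for lo, hi in zip(
        np.concatenate([[0], breaks]),
        np.concatenate([breaks, [indices.size]]),
    ):
        run_scores = scores[lo:hi]
        best = lo + int(np.argmax(run_scores) if prefer_max
                        else np.argmin(run_scores))
        w = int(indices[best])
        t_event = (
            float(times[w]) if event_times is None else float(event_times[best])
        )
        events.append(
            DetectionEvent(
                time=t_event,
                window_index=w,
                cluster=int(clusters[best]),
                score=float(scores[best]),
                method=method,
                run_first=int(indices[lo]),
                run_last=int(indices[hi - 1]),
            )
        )
    return events


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _scan_scores(
    series: OscillationSeries,
    model: TrainedModel,
    cfg: DetectorConfig,
):
    """Yield (global window indices, score, cluster, rise) per chunk.

    Shared machinery for both detectors: window extraction, normalization,
    and per-window scoring.  Scores are d^2 for MDB, best R^2 for CDB.
    """
    if not model.clusters:
        raise ValueError("model has no kept clusters")
    L = model.n_window
    M = len(series)
    if M <= L - 1:
        return
    Fw = sliding_window_view(series.f, L)
    Aw = sliding_window_view(series.A, L)
    n_windows = Fw.shape[0]  # = M - 10^r

    if cfg.method == "mdb":
        chols = [np.linalg.cholesky(c.Sigma) for c in model.clusters]
        logdets = [2.0 * np.sum(np.log(np.diag(Lc))) for Lc in chols]
        logps = [np.log(c.p) for c in model.clusters]
    else:
        means_f = np.stack([c.mean_f for c in model.clusters])  # (C*, L)

    for start in range(0, n_windows, CHUNK):
        stop = min(start + CHUNK, n_windows)
        F = np.ascontiguousarray(Fw[start:stop])
        A = np.ascontiguousarray(Aw[start:stop])
        phi, a, rise, valid = normalize_windows(F, A, cfg.n_med)
        if cfg.method == "mdb":
            Y = np.concatenate([phi, a], axis=1) @ model.P_N  # (w, N)
            N = model.N
            log_post = np.empty((Y.shape[0], len(model.clusters)))
            maha = np.empty_like(log_post)
            for c, (Lc, ld, lp) in enumerate(zip(chols, logdets, logps)):
                z = np.linalg.solve(Lc, (Y - model.clusters[c].mu).T)
                m2 = np.sum(z * z, axis=0)
                maha[:, c] = m2
                log_post[:, c] = lp - 0.5 * (N * np.log(2 * np.pi) + ld + m2)
            assign = np.argmax(log_post, axis=1)
            score = maha[np.arange(maha.shape[0]), assign]
        else:
            sst = np.sum((phi - phi.mean(axis=1, keepdims=True)) ** 2, axis=1)
            sse = (
                np.sum(phi * phi, axis=1)[:, None]
                - 2.0 * phi @ means_f.T
                + np.sum(means_f * means_f, axis=1)[None, :]
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = 1.0 - sse / sst[:, None]
            r2[sst == 0] = -np.inf
            assign = np.argmax(r2, axis=1)
            score = r2[np.arange(r2.shape[0]), assign]
        yield start, score, assign, rise, valid


def _scan(
    series: OscillationSeries, model: TrainedModel, cfg: DetectorConfig
) -> list[DetectionEvent]:
    if cfg.method == "mdb":
        eps_d2 = chi2_threshold(cfg.alpha, model.N)
    hits_idx, hits_score, hits_cluster = [], [], []
    for start, score, assign, rise, valid in _scan_scores(series, model, cfg):
        if cfg.method == "mdb":
            hit = valid & (score < eps_d2) & (rise > cfg.eps_f)
        else:
            hit = valid & (score > cfg.eps_r2) & (rise > cfg.eps_f)
        loc = np.flatnonzero(hit)
        hits_idx.append(loc + start)
        hits_score.append(score[loc])
        hits_cluster.append(assign[loc])
    if not hits_idx:
        return []
    indices = np.concatenate(hits_idx)
    scores = np.concatenate(hits_score)
    clusters = np.concatenate(hits_cluster)
    return _consolidate(
        indices, scores, clusters, series.T, cfg.method,
        prefer_max=(cfg.method == "cdb"),
    )


def mdb_scan(
    series: OscillationSeries, model: TrainedModel, cfg: DetectorConfig
) -> list[DetectionEvent]:
    """Mahalanobis-distance-based detection (see module docstring)."""
    if cfg.method != "mdb":
        cfg = DetectorConfig("mdb", cfg.eps_f, cfg.alpha, cfg.eps_r2, cfg.n_med)
    return _scan(series, model, cfg)


def cdb_scan(
    series: OscillationSeries, model: TrainedModel, cfg: DetectorConfig
) -> list[DetectionEvent]:
    """Coefficient-of-determination-based detection (see module docstring)."""
    if cfg.method != "cdb":
        cfg = DetectorConfig("cdb", cfg.eps_f, cfg.alpha, cfg.eps_r2, cfg.n_med)
    return _scan(series, model, cfg)


def events_to_rows(
    events: list[DetectionEvent], recording_id: str = ""
) -> list[dict]:
    """Flatten events for delimited-text output."""
    return [
        {
            "recording_id": recording_id,
            "method": e.method,
            "time_s": e.time,
            "window_index": e.window_index,
            "cluster": e.cluster,
            "score": e.score,
            "run_first": e.run_first,
            "run_last": e.run_last,
        }
        for e in events
    ]
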
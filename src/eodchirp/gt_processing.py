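"""Processing of annotated ground-truth chirp samples.

A ground-truth (GT) chirp sample is the run of oscillation points inside
a manually annotated time interval.  Before it can train a waveform
model it is normalized (frequency relative to the maximum rise above the
local base frequency, amplitude relative to the base amplitude),
centered on the chirp's rectified-frequency mass, trimmed to six times
its 10--90% mass width, and finally resampled to a uniform count of
``10**r + 1`` raw points taken from the parent series around the center
index.  The group index ``r`` in {1, 2, 3} separates chirp time scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_extraction import OscillationSeries

logger = logging.getLogger(__name__)

N_MED_DEFAULT = 10       # edge points pooled for base estimates
DELTA_DEFAULT = 50.0     # rectifier smoothing parameter


class SampleError(ValueError):
    """A GT sample violates a processing precondition."""


@dataclass
class ChirpAnnotation:
    recording_id: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(
                f"annotation [{self.t_start}, {self.t_end}] has t_end <= t_start"
            )


def read_annotations(path: str | Path) -> list[ChirpAnnotation]:
    """Read delimited annotations with header recording_id,t_start_s,t_end_s."""
    df = pd.read_csv(path)
    return [
        ChirpAnnotation(str(r.recording_id), float(r.t_start_s), float(r.t_end_s))
        for r in df.itertuples()
    ]


def write_annotations(anns: list[ChirpAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "recording_id": [a.recording_id for a in anns],
            "t_start_s": [a.t_start for a in anns],
            "t_end_s": [a.t_end for a in anns],
        }
    ).to_csv(path, index=False)


@dataclass
class GTSample:
    """Annotated chirp points plus their location in the parent series.

    ``source_offset`` is the index of the sample's first point within the
    parent recording's OscillationSeries, so that after centering the
    sample can be re-windowed on the raw parent points.
    """

    recording_id: str
    source_offset: int
    T: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.T.size


@dataclass
class ResampledSample:
    """A GT sample re-windowed to exactly ``10**r + 1`` parent points."""

    recording_id: str
    r: int
    source_offset: int          # parent index of the first resampled point
    T: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    a: np.ndarray = field(repr=False)

    @property
    def t_first(self) -> float:
        return float(self.T[0])

    @property
    def t_last(self) -> float:
        return float(self.T[-1])


@dataclass
class GTGroup:
    r: int
    samples: list[ResampledSample]

    @property
    def n_points(self) -> int:
        return 10 ** self.r + 1

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# sample construction and normalization
# ---------------------------------------------------------------------------

def build_gt_sample(
    series: OscillationSeries,
    ann: ChirpAnnotation,
    n_med: int = N_MED_DEFAULT,
) -> GTSample:
    """Cut the series points inside the annotated interval into a GTSample."""
    mask = (series.T >= ann.t_start) & (series.T <= ann.t_end)
    n_in = int(mask.sum())
    if n_in < 2 * n_med + 1:
        raise SampleError(
            f"annotation {ann.recording_id}[{ann.t_start:.3f},{ann.t_end:.3f}] "
            f"holds only {n_in} points (< {2 * n_med + 1})"
        )
    offset = int(np.flatnonzero(mask)[0])
    return GTSample(
        ann.recording_id,
        offset,
        series.T[mask].copy(),
        series.f[mask].copy(),
        series.A[mask].copy(),
    )


def estimate_base(
    f: np.ndarray, A: np.ndarray, n_med: int = N_MED_DEFAULT
) -> tuple[float, float]:
    """Base frequency and amplitude: median of the pooled first and last
    ``n_med`` values (the pre- and post-chirp points the annotator was
    instructed to include)."""
    if f.size < 2 * n_med + 1:
        raise SampleError(f"sample of {f.size} points too small for n_med={n_med}")
    f_base = float(np.median(np.concatenate([f[:n_med], f[-n_med:]])))
    A_base = float(np.median(np.concatenate([A[:n_med], A[-n_med:]])))
    return f_base, A_base


def normalize_sample(
    f: np.ndarray,
    A: np.ndarray,
    f_base: float,
    A_base: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized frequency phi (peak rise = 1) and relative amplitude a.

    phi = (f - f_base) / (max f - f_base); a = (A - A_base) / A_base.
    """
    rise = float(np.max(f)) - f_base
    if rise <= 0:
        raise SampleError("no frequency rise above base: cannot normalize")
    if A_base == 0:
        raise SampleError("zero base amplitude: cannot normalize")
    phi = (f - f_base) / rise
    a = (A - A_base) / A_base
    return phi, a


# ---------------------------------------------------------------------------
# rectified centering and trimming
# ---------------------------------------------------------------------------

def rectify(
    phi: np.ndarray | float, phi_bar: float, delta: float = DELTA_DEFAULT
) -> np.ndarray | float:
    """Softplus rectifier h(phi) = ln(1 + exp(delta(|phi| - phi_bar))) / (delta - delta*phi_bar).

    Suppresses sub-cutoff noise while growing linearly for large rises;
    evaluated via logaddexp so large arguments cannot overflow.
    """
    if not 0 <= phi_bar < 1:
        raise ValueError(f"cutoff phi_bar={phi_bar} must lie in [0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = delta * (np.abs(phi) - phi_bar)
    return np.logaddexp(0.0, x) / (delta - delta * phi_bar)


def cutoff(phi: np.ndarray, n_med: int = N_MED_DEFAULT) -> float:
    """Noise cutoff: 4x the larger sample sd of the first/last n_med phi."""
    if phi.size < 2 * n_med:
        raise SampleError("sample too small for cutoff estimation")
    sd_head = float(np.std(phi[:n_med], ddof=1))
    sd_tail = float(np.std(phi[-n_med:], ddof=1))
    return 4.0 * max(sd_head, sd_tail)


def rectified_cdf(
    phi: np.ndarray, phi_bar: float, delta: float = DELTA_DEFAULT
) -> np.ndarray:
    """Empirical cumulative distribution H of the rectified frequencies."""
    h = rectify(phi, phi_bar, delta)
    total = float(np.sum(h))
    if total <= 0:
        raise SampleError("degenerate sample: zero rectified mass")
    return np.cumsum(h) / total


def center_index(H: np.ndarray) -> int:
    """Index where H crosses one half (argmin |H - 1/2|, first on ties)."""
    return int(np.argmin(np.abs(H - 0.5)))


def trim_width(H: np.ndarray, T_centered: np.ndarray) -> float:
    """10--90% mass width of the centered sample."""
    j_plus = int(np.argmin(np.abs(H - 0.9)))
    j_minus = int(np.argmin(np.abs(H - 0.1)))
    width = float(T_centered[j_plus] - T_centered[j_minus])
    if width <= 0:
        raise SampleError("degenerate width: 10-90% mass interval collapsed")
    return width


def trim_sample(
    sample: GTSample,
    n_med: int = N_MED_DEFAULT,
    delta: float = DELTA_DEFAULT,
) -> tuple[np.ndarray, int]:
    """Center and trim a sample to points with centered time in
    [-3*width, 3*width].

    Returns
    -------
    keep : boolean mask over the sample's points
    j_cen : center index (into the untrimmed sample)
    """
    f_base, A_base = estimate_base(sample.f, sample.A, n_med)
    phi, _ = normalize_sample(sample.f, sample.A, f_base, A_base)
    phi_bar = cutoff(phi, n_med)
    if phi_bar >= 1:
        # edge noise as large as the peak rise itself: nothing to center on
        raise SampleError(f"noise cutoff {phi_bar:.3f} >= 1; sample is noise")
    H = rectified_cdf(phi, phi_bar, delta)
    j_cen = center_index(H)
    T_cen = sample.T - sample.T[j_cen]
    width = trim_width(H, T_cen)
    keep = (T_cen >= -3 * width) & (T_cen <= 3 * width)
    return keep, j_cen


# ---------------------------------------------------------------------------
# grouping and resampling
# ---------------------------------------------------------------------------

def _group_for_count(count: int) -> int | None:
    """Group r with count in (10**(r-1) + 1, 10**r + 1]; counts above the
    largest group are clamped to r=3 (chirps longer than ~0.5 s do not
    occur, so this only ever fires on pathological annotations)."""
    for r in (1, 2, 3):
        if 10 ** (r - 1) + 1 < count <= 10 ** r + 1:
            return r
    if count > 10 ** 3 + 1:
        logger.warning("trimmed sample of %d points clamped to group 3", count)
        return 3
    return None


def group_and_resample(
    samples: list[GTSample],
    series_map: dict[str, OscillationSeries],
    n_med: int = N_MED_DEFAULT,
    delta: float = DELTA_DEFAULT,
) -> dict[int, GTGroup]:
    """Assign each sample to a time-scale group and re-window it.

    The trimmed point count picks the group r; the resampled sample is the
    ``10**r + 1`` raw parent-series points centered on the sample's center
    index (no interpolation).  phi and a are then recomputed from the raw
    resampled points.  Samples that are too short, whose window overruns
    the recording, or that lose their frequency rise are dropped (logged).
    """
    groups: dict[int, list[ResampledSample]] = {1: [], 2: [], 3: []}
    for idx, sample in enumerate(samples):
        try:
            keep, j_cen = trim_sample(sample, n_med, delta)
        except SampleError as exc:
            logger.warning("sample %d dropped: %s", idx, exc)
            continue
        count = int(keep.sum())
        if count <= 2:
            logger.warning("sample %d dropped: trimmed to %d points", idx, count)
            continue
        r = _group_for_count(count)
        if r is None:  # count <= 2 already handled; unreachable for count >= 3
            continue
        half = 10 ** r // 2
        series = series_map[sample.recording_id]
        p_cen = sample.source_offset + j_cen
        p_lo, p_hi = p_cen - half, p_cen + half
        if p_lo < 0 or p_hi >= len(series):
            logger.warning(
                "sample %d dropped: resampling window [%d, %d] outside recording",
                idx, p_lo, p_hi,
            )
            continue
        sl = slice(p_lo, p_hi + 1)
        T, f, A = series.T[sl].copy(), series.f[sl].copy(), series.A[sl].copy()
        try:
            f_base, A_base = estimate_base(f, A, n_med)
            phi, a = normalize_sample(f, A, f_base, A_base)
        except SampleError as exc:
            logger.warning("sample %d dropped after resampling: %s", idx, exc)
            continue
        groups[r].append(
            ResampledSample(sample.recording_id, r, p_lo, T, f, A, phi, a)
        )
    return {r: GTGroup(r, lst) for r, lst in groups.items()}
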
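"""Configuration, model serialization, and seeded pipeline glue.

The model container is plain JSON: Python's JSON writer emits the
shortest repr that round-trips each float64, so save/load restores every
array bit-exactly.  A single top-level seed is fanned out to per-stage
seeds by a fixed derivation, so one knob reproduces the whole pipeline.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import SegmentData
from .gt_processing import (
    DELTA_DEFAULT,
    N_MED_DEFAULT,
    ChirpAnnotation,
    GTGroup,
    build_gt_sample,
    group_and_resample,
)
from .model_training import (
    DELTA_C_DEFAULT,
    DELTA_R2_DEFAULT,
    GaussianCluster,
    TrainedModel,
)
from .signal_extraction import (
    DEFAULT_SEARCH_BAND,
    OscillationSeries,
    Segment,
)

MODEL_FORMAT_VERSION = 1


class ModelFileError(ValueError):
    """The model file is missing, truncated, or of an incompatible version."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Units: times in seconds, frequencies in Hz.  ``n_med`` is the number
    of edge points pooled for base-frequency/amplitude estimates;
    ``delta`` the rectifier smoothing; ``delta_r2``/``delta_c`` the
    cluster-elimination thresholds.
    """

    window_s: float = 3.0
    overlap_s: float = 2.0
    search_band_lo: float = DEFAULT_SEARCH_BAND[0]
    search_band_hi: float = DEFAULT_SEARCH_BAND[1]
    filter_order: int = 4
    n_med: int = N_MED_DEFAULT
    delta: float = DELTA_DEFAULT
    delta_r2: float = DELTA_R2_DEFAULT
    #: minimum cluster size; None scales it to the training-set size
    delta_c: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_s >= self.window_s:
            raise ValueError("overlap_s must be smaller than window_s")
        if not 0 < self.search_band_lo < self.search_band_hi:
            raise ValueError("invalid search band")
        if self.n_med < 1 or self.filter_order < 1:
            raise ValueError("n_med and filter_order must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "r": model.r,
        "N": model.N,
        "P_N": model.P_N.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "clusters": [
            {
                "mu": c.mu.tolist(),
                "Sigma": c.Sigma.tolist(),
                "p": c.p,
                "mean_f": c.mean_f.tolist(),
                "mean_a": c.mean_a.tolist(),
            }
            for c in model.clusters
        ],
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot read model file {path}: {exc}") from exc
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"incompatible model file version {payload.get('format_version')!r}"
        )
    clusters = [
        GaussianCluster(
            mu=np.array(c["mu"]),
            Sigma=np.array(c["Sigma"]),
            p=float(c["p"]),
            mean_f=np.array(c["mean_f"]),
            mean_a=np.array(c["mean_a"]),
        )
        for c in payload["clusters"]
    ]
    return TrainedModel(
        r=int(payload["r"]),
        N=int(payload["N"]),
        P_N=np.array(payload["P_N"]),
        eigenvalues=np.array(payload["eigenvalues"]),
        clusters=clusters,
        metadata=payload["metadata"],
    )


# ---------------------------------------------------------------------------
# pipeline helpers
# ---------------------------------------------------------------------------

def prepare_gt_groups(
    series: OscillationSeries,
    annotations: list[ChirpAnnotation],
    recording_id: str = "rec",
    n_med: int = N_MED_DEFAULT,
    delta: float = DELTA_DEFAULT,
) -> dict[int, GTGroup]:
    """Annotations + series -> processed, grouped, resampled GT samples."""
    samples = []
    for ann in annotations:
        ann = ChirpAnnotation(recording_id, ann.t_start, ann.t_end)
        samples.append(build_gt_sample(series, ann, n_med))
    return group_and_resample(samples, {recording_id: series}, n_med, delta)


def segments_with_gt(
    segments: list[Segment], group: GTGroup
) -> list[SegmentData]:
    """Attach each GT sample to the segment containing its center time."""
    out = []
    for seg in segments:
        members = [
            s
            for s in group.samples
            if seg.t_lo <= 0.5 * (s.t_first + s.t_last) < seg.t_hi
        ]
        out.append(SegmentData(seg.index, seg.points, members))
    return out


# ---------------------------------------------------------------------------
# cross-validation glue
# ---------------------------------------------------------------------------

def default_grid(method: str, small: bool = False) -> dict:
    """Hyperparameter search domains per detection method.

    The full domains are the published search grids; ``small=True``
    selects a reduced sub-grid for quick desk-scale runs.
    """
    eps_f = list(range(0, 22, 2))
    eps_r2 = [round(0.3 + 0.05 * i, 2) for i in range(11)]  # 0.3 .. 0.8
    if method == "mdb":
        grid = {
            "N": list(range(2, 9)),
            "C": list(range(2, 15)),
            "eps_f": eps_f,
            "alpha": [round(0.01 * i, 2) for i in range(1, 16)],
        }
        if small:
            grid.update(N=[2, 3], C=[2, 3], eps_f=[10, 20],
                        alpha=[0.01, 0.05, 0.10])
    elif method == "cdb":
        grid = {
            "N": list(range(2, 9)),
            "C": list(range(2, 15)),
            "eps_f": eps_f,
            "eps_r2": eps_r2,
        }
        if small:
            grid.update(N=[2, 3], C=[2, 3], eps_f=[10, 20],
                        eps_r2=[0.3, 0.5, 0.7])
    elif method == "tfsb":
        grid = {"eps_f": eps_f, "eps_r2": eps_r2}
        if small:
            grid.update(eps_f=[10, 20], eps_r2=[0.3, 0.5, 0.7])
    else:
        raise ValueError(f"unknown method {method!r}")
    return grid


def scaled_delta_c(m_train: int) -> int:
    """Minimum cluster size scaled to the training-set size.

    The published threshold of 30 presumes training sets of hundreds of
    samples; a homogeneous set of m samples split over C clusters can
    only survive if the threshold stays below m/C, so for small studies
    we use a quarter of the training-set size, capped at the default.
    """
    return min(DELTA_C_DEFAULT, max(2, m_train // 4))


def make_detector_factory(
    method: str, r: int, seed: int, delta_c: int | None = None
):
    """Detector factory for cross_validate.

    For the supervised methods the trained model depends only on (N, C)
    and the training set, so models are cached across threshold-only
    hyperparameter changes; the TFSB template needs no training at all.
    Returned detectors map an OscillationSeries to detected chirp times.
    ``delta_c=None`` scales the minimum cluster size to the training-set
    size via :func:`scaled_delta_c`.
    """
    from .chirp_detection import DetectorConfig, cdb_scan, mdb_scan
    from .model_training import train_model
    from .tfsb import TFSBParams, tfsb_scan

    if method == "tfsb":

        def factory(h: dict, train_samples):
            params = TFSBParams(eps_f=h["eps_f"], eps_r2=h["eps_r2"])

            def detect(series):
                return [e.time for e in tfsb_scan(series, params)]

            return detect

        return factory

    if method not in ("mdb", "cdb"):
        raise ValueError(f"unknown method {method!r}")
    scan = mdb_scan if method == "mdb" else cdb_scan
    cache: dict[tuple, TrainedModel] = {}

    def factory(h: dict, train_samples):
        key = (
            h["N"],
            h["C"],
            tuple((s.recording_id, s.source_offset) for s in train_samples),
        )
        if key not in cache:
            group = GTGroup(r, list(train_samples))
            dc = scaled_delta_c(len(train_samples)) if delta_c is None else delta_c
            cache[key] = train_model(group, h["N"], h["C"], seed, delta_c=dc)
        model = cache[key]
        cfg = DetectorConfig(
            method,
            eps_f=h["eps_f"],
            alpha=h.get("alpha", 0.05),
            eps_r2=h.get("eps_r2", 0.5),
        )

        def detect(series):
            return [e.time for e in scan(series, model, cfg)]

        return detect

    return factory
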
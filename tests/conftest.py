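"""Shared fixtures: a small synthetic EOD study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import eodchirp as ec


@pytest.fixture(scope="session")
def synth_study():
    """120 s of 750 Hz carrier with 20 scheduled type-2 chirps.

    Returns (trace, annotations, oscillation series); the one moderately
    expensive fixture, shared session-wide.
    """
    spec = ec.preset_types()["type2"]
    schedule = ec.regular_schedule(120.0, 20, spec, seed=7)
    trace, anns = ec.synthesize(schedule)
    series = ec.extract_oscillations(trace)
    return trace, anns, series


@pytest.fixture(scope="session")
def g2_group(synth_study):
    """Processed ground-truth group r=2 (101-point samples) of the study."""
    _, anns, series = synth_study
    groups = ec.prepare_gt_groups(series, anns)
    assert len(groups[2]) == 20
    return groups[2]


@pytest.fixture(scope="session")
def trained_model(g2_group):
    """Waveform model trained on all 20 study samples (N=2, C=2).

    delta_c is scaled to the small training set as in any desk-scale run.
    """
    from eodchirp.workbench import scaled_delta_c

    return ec.train_model(
        g2_group, N=2, C=2, seed=17, delta_c=scaled_delta_c(len(g2_group))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
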
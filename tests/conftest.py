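"""Shared fixtures and helpers for the test suite.

All fixtures generate data programmatically through the synthetic-data
module; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pnisig import pipeline, synthdata as sd

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def null_acute_scenario(**kw) -> sd.AcuteScenario:
    """Noise-only acute scenario (no evoked component, no artifact)."""
    params = dict(
        currents=[0.0],
        trials_per_current=16,
        isi_s=0.05,
        artifact_amp=0.0,
        noise=sd.post_plating_noise(),
    )
    params.update(kw)
    return sd.AcuteScenario(**params)


def small_chronic_scenario(**kw) -> sd.ChronicScenario:
    """Down-scaled chronic scenario for fast pipeline runs (lower fs,
    matching narrower noise band, short motif)."""
    params = dict(
        n_channels=4,
        motif_len_ms=300,
        renditions_per_day=8,
        fs=8000.0,
        noise=sd.NoisePreset(rms=1.0, band=(1.0, 3000.0)),
        spike_rate=300.0,
        gap_s=0.15,
    )
    params.update(kw)
    return sd.ChronicScenario(**params)


CHRONIC_BAND = (300.0, 3000.0)


def chronic_aligned(scenario, seed=0, day=0, template=None):
    rec, motifs, gt = sd.gen_chronic_session(scenario, day=day, seed=seed, with_audio=False)
    aligned, template = pipeline.chronic_aligned_envelopes(
        rec, motifs, gt.audio_features, band=CHRONIC_BAND, template=template
    )
    return aligned, template, (rec, motifs, gt)


@pytest.fixture(scope="session")
def acute_session_small():
    """One small acute session with evoked responses at several currents."""
    sc = sd.standard_acute_scenario(trials_per_current=4, isi_s=0.05)
    rec, events, gt = sd.gen_acute_session(sc, seed=11)
    return sc, rec, events, gt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
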
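"""Shared fixtures: simulated subjects processed through the radar chain.

Everything is generated at test time from fixed seeds; session scope and an
argument cache keep each simulated subject's feature extraction to a single
run across the suite.
"""
from __future__ import annotations

import numpy as np
import pytest

from radarhrv import (
    SimulationConfig,
    demodulate,
    extract_features,
    simulate_record,
)
from radarhrv.pipeline import truth_feature_labels


@pytest.fixture(scope="session")
def subject_factory():
    """Memoised builder of fully processed simulated subjects.

    Returns ``(track, labels, truth, cfg)`` for a given seed / duration /
    mean RR / detector noise.
    """
    cache: dict = {}

    def make(seed: int, duration: float = 120.0, mean_rr: float = 1.0,
             noise_sd: float = 0.01):
        key = (seed, duration, mean_rr, noise_sd)
        if key not in cache:
            cfg = SimulationConfig(duration=duration, mean_rr=mean_rr,
                                   noise_sd=noise_sd, seed=seed)
            rec, truth = simulate_record(cfg)
            disp = demodulate(rec, cfg.wavelength)
            track, _ = extract_features(disp)
            labels = truth_feature_labels(truth, track.feature_fs,
                                          track.n_frames)
            cache[key] = (track, labels, truth, cfg)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def hsmm_subjects(subject_factory):
    """Six clean two-minute subjects spanning 57-92 bpm for HSMM tests."""
    return [subject_factory(10 + i, duration=120.0, mean_rr=0.65 + 0.08 * i)
            for i in range(6)]


@pytest.fixture(scope="session")
def losocv_subjects(subject_factory):
    """Six three-minute subjects at moderate detector noise for LOSOCV."""
    return [subject_factory(20 + i, duration=180.0, mean_rr=0.78 + 0.05 * i)
            for i in range(6)]


@pytest.fixture(scope="session")
def trained_hsmm(hsmm_subjects):
    """HSMM trained on the first five subjects (the sixth is held out)."""
    from radarhrv import train_hsmm

    return train_hsmm([s[0] for s in hsmm_subjects[:5]],
                      [s[1] for s in hsmm_subjects[:5]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
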
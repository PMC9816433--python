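"""Shared fixtures: simulated subjects at various scales.

All fixtures are deterministic; the heavier ones (full default subject plus
its ICA decomposition) are session-scoped so the correction and acceptance
tests share one simulation.
"""

import numpy as np
import pytest

from bcg_preserve.core_io import Recording
from bcg_preserve.synthetic import SimulationConfig, assemble_subject
from bcg_preserve.preprocess import bandpass
from bcg_preserve.correction import ga_aas, fit_ica


@pytest.fixture(scope="session")
def default_subject():
    """One full subject at default (study-condition) parameters."""
    cfg = SimulationConfig(seed=7)
    rec, gt = assemble_subject(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def prepped_subject(default_subject):
    """Default subject after gradient AAS and 1-50 Hz band-pass."""
    cfg, rec, gt = default_subject
    eeg = rec.pick(list(cfg.channels))
    ga_fixed, _ = ga_aas(eeg)
    filt = bandpass(ga_fixed, 1.0, 50.0)
    return cfg, rec, gt, filt


@pytest.fixture(scope="session")
def subject_ica(prepped_subject):
    """ICA decomposition of the prepped default subject."""
    cfg, rec, gt, filt = prepped_subject
    return fit_ica(filt, seed=7)


@pytest.fixture
def small_cfg():
    """A light-weight configuration for unit tests (40 s)."""
    return SimulationConfig(seed=3, duration_s=40.0)


def make_recording(data, fs=1000.0, labels=None, events=()):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(list(labels), fs, data, list(events))
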
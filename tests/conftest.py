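"""Shared fixtures: reduced-scale acquisitions keep the suite fast while
preserving the spectral resolution (< 2 Hz/point) the analysis assumes."""

from __future__ import annotations

import numpy as np
import pytest

from fmrspipe import (
    AcquisitionParams,
    SubjectTruth,
    TaskDesign,
    build_schedule,
    simulate_transients,
)
from fmrspipe.preprocess import register_spectra

# 4 task blocks -> 280 transients of 1024 points: every pipeline stage is
# exercised with ~1.95 Hz/point resolution at a fraction of the full-run cost.
REDUCED_PARAMS = AcquisitionParams(n_points=1024, n_transients=280)
REDUCED_DESIGN = TaskDesign(n_on_blocks=4)

#: truth with every stochastic term switched off (deterministic signal model)
CLEAN_TRUTH = dict(
    noise_sd=0.0,
    fwhm_noise_sd_hz=0.0,
    drift_hz_per_min=0.0,
    motion_spike_prob=0.0,
    pc_offset=0.0 + 0.0j,
)


@pytest.fixture(scope="session")
def reduced_params() -> AcquisitionParams:
    return REDUCED_PARAMS


@pytest.fixture(scope="session")
def reduced_design() -> TaskDesign:
    return REDUCED_DESIGN


@pytest.fixture(scope="session")
def reduced_schedule():
    return build_schedule(REDUCED_PARAMS, REDUCED_DESIGN, seed=11)


@pytest.fixture(scope="session")
def clean_series(reduced_schedule):
    """Noiseless simulated series (BOLD and task effect still present)."""
    truth = SubjectTruth(**CLEAN_TRUTH)
    return simulate_transients(reduced_schedule, truth, REDUCED_PARAMS, seed=21)


@pytest.fixture(scope="session")
def noisy_series(reduced_schedule):
    """Realistic-noise simulated series with default contamination."""
    truth = SubjectTruth()
    return simulate_transients(reduced_schedule, truth, REDUCED_PARAMS, seed=22)


@pytest.fixture(scope="session")
def registered_noisy(noisy_series):
    return register_spectra(noisy_series)
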
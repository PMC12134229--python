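"""Dual-gamma haemodynamic response function and event regressors."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma

from .params import HRFParams

__all__ = ["double_gamma", "event_regressor"]


def double_gamma(t: np.ndarray, params: HRFParams | None = None) -> np.ndarray:
    """Evaluate the canonical dual-gamma HRF at times ``t`` (seconds).

    Positive-lobe gamma density minus a scaled undershoot gamma density,
    normalised so the kernel peak equals 1. Zero for t < 0 and
    t > ``params.length_s``.
    """
    params = params or HRFParams()
    t = np.asarray(t, dtype=float)
    a1 = params.peak_delay_s / params.peak_disp
    a2 = params.undershoot_delay_s / params.undershoot_disp
    h = gamma.pdf(t, a1, scale=params.peak_disp) - gamma.pdf(
        t, a2, scale=params.undershoot_disp
    ) / params.ratio
    h = np.where((t < 0) | (t > params.length_s), 0.0, h)
    # normalise to unit peak on a fine grid so sampling does not change scale
    tt = np.linspace(0.0, params.length_s, 4001)
    hh = gamma.pdf(tt, a1, scale=params.peak_disp) - gamma.pdf(
        tt, a2, scale=params.undershoot_disp
    ) / params.ratio
    peak = hh.max()
    if peak <= 0:
        raise ValueError("degenerate HRF parameters: non-positive peak")
    return h / peak


def event_regressor(
    event_times_s: np.ndarray,
    sample_times_s: np.ndarray,
    params: HRFParams | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Unit impulses at ``event_times_s`` convolved with the dual-gamma kernel.

    The convolution of a Dirac train with the kernel is evaluated exactly as a
    kernel sum, r(t) = sum_e h(t - t_e), at the requested sample times, then
    (optionally) normalised to peak 1 over those samples.
    """
    events = np.asarray(event_times_s, dtype=float)
    samples = np.asarray(sample_times_s, dtype=float)
    if events.size == 0:
        return np.zeros_like(samples)
    lags = samples[:, None] - events[None, :]
    r = double_gamma(lags.ravel(), params).reshape(lags.shape).sum(axis=1)
    if normalize:
        peak = np.abs(r).max()
        if peak > 0:
            r = r / peak
    return r
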
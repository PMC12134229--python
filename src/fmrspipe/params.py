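"""Acquisition, task-design and HRF parameter sets.

These dataclasses pin down the interleaved GABA-edited acquisition that the
rest of the package assumes: a MEGA-PRESS sequence (editing pulses alternating
between 1.9 and 7.46 ppm) with water suppression disabled on every third
transient so that an unsuppressed water reference (WREF) is interleaved with
the metabolite acquisition, run concurrently with a block-event flanker task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParams", "TaskDesign", "HRFParams", "FMRI_DESIGN"]


class ConfigurationError(ValueError):
    """Raised when parameter sets are internally inconsistent."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and spectral parameters of the interleaved MEGA-PRESS sequence.

    Defaults describe a 3 T acquisition: TE 68 ms, TR 1.5 s, 700 transients,
    2-step phase cycle, water reference every third transient.
    """

    te_s: float = 0.068
    tr_s: float = 1.5
    edit_on_ppm: float = 1.9
    edit_off_ppm: float = 7.46
    n_transients: int = 700
    wref_every: int = 3
    phase_cycle_steps: int = 2
    n_points: int = 2048
    spectral_width_hz: float = 2000.0
    f0_mhz: float = 127.7
    water_ppm: float = 4.68

    def __post_init__(self) -> None:
        if self.n_transients <= 0:
            raise ConfigurationError("n_transients must be positive")
        if self.wref_every < 2:
            raise ConfigurationError("wref_every must be >= 2")
        if self.spectral_width_hz / self.n_points >= 2.0:
            raise ConfigurationError(
                "frequency resolution spectral_width_hz/n_points must be < 2 Hz"
            )
        for name in ("edit_on_ppm", "edit_off_ppm", "water_ppm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise ConfigurationError(f"{name}={v} outside [0, 10] ppm")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def hz_per_point(self) -> float:
        return self.spectral_width_hz / self.n_points

    def time_axis(self) -> np.ndarray:
        """FID sample times in seconds (0, dwell, 2*dwell, ...)."""
        return np.arange(self.n_points) * self.dwell_s

    def ppm_to_hz(self, ppm: float | np.ndarray) -> float | np.ndarray:
        """Offset frequency (Hz) of a chemical shift relative to the carrier."""
        return (np.asarray(ppm) - self.water_ppm) * self.f0_mhz


@dataclass(frozen=True)
class TaskDesign:
    """Block-event flanker design: 60 s OFF then alternating 30 s ON / 60 s OFF.

    One trial is presented per TR during ON blocks, with onset jittered so the
    stimulus precedes the excitation pulse by T_S-A in ``jitter_range_s``.
    Defaults give the 11-block spectroscopy session (220 trials, 1050 s); the
    6-block imaging variant is available as :data:`FMRI_DESIGN`.
    """

    initial_off_s: float = 60.0
    on_block_s: float = 30.0
    off_block_s: float = 60.0
    n_on_blocks: int = 11
    isi_s: float = 1.5
    p_incongruent: float = 0.4
    stim_duration_s: float = 0.35
    response_window_s: float = 0.8
    jitter_range_s: tuple[float, float] = (0.100, 0.350)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_incongruent <= 1.0:
            raise ConfigurationError("p_incongruent must lie in [0, 1]")
        lo, hi = self.jitter_range_s
        if not lo < hi:
            raise ConfigurationError("jitter_range_s lower bound must be < upper")
        for name in ("initial_off_s", "on_block_s", "off_block_s"):
            dur = getattr(self, name)
            if abs(dur / self.isi_s - round(dur / self.isi_s)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={dur} is not an integer multiple of isi_s={self.isi_s}"
                )

    @property
    def total_duration_s(self) -> float:
        return self.initial_off_s + self.n_on_blocks * (self.on_block_s + self.off_block_s)

    @property
    def n_trials(self) -> int:
        return self.n_on_blocks * int(round(self.on_block_s / self.isi_s))


#: The 6-block BOLD-fMRI variant of the task (120 trials, 600 s).
FMRI_DESIGN = TaskDesign(n_on_blocks=6)


@dataclass(frozen=True)
class HRFParams:
    """Canonical dual-gamma haemodynamic response function parameters."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ConfigurationError("HRF delays must be positive")
        if self.ratio <= 0:
            raise ConfigurationError("HRF peak:undershoot ratio must be positive")


def voxel_volume_ml(dims_mm: tuple[float, float, float] = (22.0, 36.0, 23.0)) -> float:
    """Volume in millilitres of a cuboid voxel given its dimensions in mm.

    Defaults to the anterior-cingulate spectroscopy voxel (22 x 36 x 23 mm).
    """
    x, y, z = dims_mm
    return x * y * z / 1000.0
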
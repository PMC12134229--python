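"""Frequency-domain spectrum container and FID <-> spectrum conversion.

Conventions used throughout the package:

* FIDs are complex time-domain arrays sampled at ``1/spectral_width_hz``.
* Spectra approximate the continuous Fourier transform: ``fftshift(fft(fid)) *
  dwell``, so a damped exponential of time-domain amplitude A integrates to an
  absorption-mode (real-part) peak area of A/2 independent of linewidth.
* The ppm axis is stored decreasing left-to-right (highest chemical shift
  first), anchored at the water resonance (4.68 ppm) on the carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import AcquisitionParams

__all__ = ["Spectrum", "fid_to_spectrum", "spectrum_to_fid"]


@dataclass
class Spectrum:
    """Complex spectrum on a strictly decreasing ppm axis."""

    values: np.ndarray
    ppm_axis: np.ndarray
    f0_mhz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        if self.values.shape != self.ppm_axis.shape:
            raise ValueError("values and ppm_axis must have identical shape")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm_axis must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    @property
    def hz_per_ppm(self) -> float:
        return self.f0_mhz

    def region(self, ppm_lo: float, ppm_hi: float) -> np.ndarray:
        """Boolean mask selecting ppm in the half-open interval [lo, hi)."""
        return (self.ppm_axis >= ppm_lo) & (self.ppm_axis < ppm_hi)

    def crop(self, ppm_lo: float, ppm_hi: float) -> "Spectrum":
        m = self.region(ppm_lo, ppm_hi)
        if not m.any():
            raise ValueError(f"no points in ppm window [{ppm_lo}, {ppm_hi})")
        return Spectrum(self.values[m], self.ppm_axis[m], self.f0_mhz)

    def area(self, ppm_lo: float, ppm_hi: float) -> float:
        """Integral of the real part over a ppm window, in amplitude*1 units.

        The integration step is in Hz so areas compare directly with
        time-domain amplitudes (area = A/2 for a full resonance).
        """
        m = self.region(ppm_lo, ppm_hi)
        df_hz = abs(np.diff(self.ppm_axis).mean()) * self.f0_mhz
        return float(self.values.real[m].sum() * df_hz)


def fid_to_spectrum(fid: np.ndarray, params: AcquisitionParams) -> Spectrum:
    """Fourier transform a FID into a :class:`Spectrum` (decreasing ppm axis)."""
    fid = np.asarray(fid).copy()
    n = fid.size
    dwell = params.dwell_s
    fid[0] = fid[0] / 2.0  # first-point halving: trapezoidal FT, flat baseline
    vals = np.fft.fftshift(np.fft.fft(fid)) * dwell
    freq = np.fft.fftshift(np.fft.fftfreq(n, d=dwell))
    ppm = params.water_ppm + freq / params.f0_mhz
    # reverse so index 0 carries the highest chemical shift
    return Spectrum(vals[::-1].copy(), ppm[::-1].copy(), params.f0_mhz)


def spectrum_to_fid(spec: Spectrum, params: AcquisitionParams) -> np.ndarray:
    """Invert :func:`fid_to_spectrum`."""
    vals = spec.values[::-1] / params.dwell_s
    fid = np.fft.ifft(np.fft.ifftshift(vals))
    fid[0] = fid[0] * 2.0
    return fid
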
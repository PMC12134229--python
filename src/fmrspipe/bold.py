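"""BOLD estimation from the unsuppressed water linewidth time series.

Each water-reference (wref) spectrum is fitted with a pseudo-Voigt on a linear
baseline; the fitted linewidth series is cleaned of outliers and
discontinuities and regressed on the HRF-convolved trial-impulse model.
Activation lengthens T2* and narrows the water line, so the BOLD model
coefficient is negative during activation; the reported BOLD-fMRS measure
``delta_fwhm_hz`` is the negated coefficient, making larger values mean a
stronger BOLD response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .hrf import event_regressor
from .params import HRFParams
from .schedule import AcquisitionSchedule
from .simulate import TransientSeries
from .spectra import Spectrum, fid_to_spectrum

__all__ = [
    "LinewidthSeries",
    "BoldEstimate",
    "fit_wref",
    "linewidth_series",
    "clean_series",
    "build_bold_regressor",
    "estimate_bold",
]

SIGN_CONVENTION = (
    "activation => narrowing; reported value = -coefficient so larger = stronger BOLD"
)


@dataclass
class LinewidthSeries:
    """Fitted water linewidth per wref transient, with validity flags."""

    onset_s: np.ndarray
    fwhm_hz: np.ndarray
    eta: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.onset_s)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class BoldEstimate:
    delta_fwhm_hz: float
    se: float
    tstat: float
    n_used: int
    reliable: bool = True
    sign_convention: str = SIGN_CONVENTION


def _pseudo_voigt(x, h, c, fwhm, eta, b0, b1):
    g = np.exp(-4.0 * np.log(2.0) * ((x - c) / fwhm) ** 2)
    l = 1.0 / (1.0 + (2.0 * (x - c) / fwhm) ** 2)
    return h * (eta * l + (1.0 - eta) * g) + b0 + b1 * (x - c)


def fit_wref(
    spectrum: Spectrum, water_ppm: float = 4.68, window_ppm: float = 1.0
) -> tuple[float, float, float, tuple[float, float]]:
    """Fit the water resonance with a pseudo-Voigt on a linear baseline.

    Returns ``(fwhm_hz, eta, amplitude, baseline)`` where eta is the
    Lorentzian fraction of the shared-width mixture. Raises ``RuntimeError``
    on non-convergence (callers mark the sample invalid).
    """
    f0 = spectrum.f0_mhz
    m = spectrum.region(water_ppm - window_ppm, water_ppm + window_ppm)
    x, y = spectrum.ppm_axis[m], spectrum.real[m]
    if x.size < 10 or np.ptp(y) == 0:
        raise RuntimeError("degenerate water window")
    i_pk = int(np.argmax(y))
    h0 = y[i_pk] - np.median(y)
    p0 = [h0, x[i_pk], 8.0 / f0, 0.5, float(np.median(y)), 0.0]
    lb = [0.0, water_ppm - window_ppm, 0.5 / f0, 0.0, -np.inf, -np.inf]
    ub = [np.inf, water_ppm + window_ppm, 100.0 / f0, 1.0, np.inf, np.inf]
    popt, _ = curve_fit(_pseudo_voigt, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    h, c, w, eta, b0, b1 = popt
    return float(w * f0), float(eta), float(h), (float(b0), float(b1))


def linewidth_series(series: TransientSeries) -> LinewidthSeries:
    """Fit every wref transient, producing the raw linewidth time series."""
    sched = series.schedule
    idx = np.where(sched.is_wref)[0]
    if idx.size == 0:
        raise ValueError("series contains no water-reference transients")
    fwhm = np.full(idx.size, np.nan)
    eta = np.full(idx.size, np.nan)
    valid = np.zeros(idx.size, dtype=bool)
    for j, i in enumerate(idx):
        try:
            fwhm[j], eta[j], _, _ = fit_wref(
                fid_to_spectrum(series.fids[i], series.params),
                water_ppm=series.params.water_ppm,
            )
            valid[j] = np.isfinite(fwhm[j]) and fwhm[j] > 0
        except (RuntimeError, ValueError):
            pass
    return LinewidthSeries(
        onset_s=sched.onsets[idx], fwhm_hz=fwhm, eta=eta, valid=valid
    )


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def clean_series(
    series: LinewidthSeries,
    mad_factor: float = 5.0,
    jump_mad_factor: float = 3.0,
    min_valid: int = 10,
) -> LinewidthSeries:
    """Invalidate outliers and discontinuities in the linewidth series.

    Two rules over currently valid samples: (1) level outliers,
    ``|x - median| > mad_factor * MAD``; (2) jumps — both samples adjacent to
    a first difference exceeding ``jump_mad_factor`` times the MAD of first
    differences. Invalid samples are excluded, never interpolated.
    """
    if series.n_valid < min_valid:
        raise ValueError(f"need >= {min_valid} valid samples, have {series.n_valid}")
    valid = series.valid.copy()
    sel = np.where(valid)[0]
    x = series.fwhm_hz[sel]
    med, mad = np.median(x), _mad(x)
    if mad > 0:
        valid[sel[np.abs(x - med) > mad_factor * mad]] = False

    sel = np.where(valid)[0]
    if sel.size >= 3:
        d = np.diff(series.fwhm_hz[sel])
        dmad = _mad(d)
        if dmad > 0:
            big = np.abs(d - np.median(d)) > jump_mad_factor * dmad
            bad = np.unique(np.concatenate([sel[:-1][big], sel[1:][big]]))
            valid[bad] = False
    return LinewidthSeries(
        onset_s=series.onset_s,
        fwhm_hz=series.fwhm_hz,
        eta=series.eta,
        valid=valid,
    )


def build_bold_regressor(
    schedule: AcquisitionSchedule,
    hrf: HRFParams | None = None,
    sample_times_s: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved trial impulses sampled at the wref onsets (peak 1)."""
    events = schedule.trial_onsets()
    if events.size == 0:
        raise ValueError("schedule contains no trial events")
    if sample_times_s is None:
        sample_times_s = schedule.onsets[schedule.is_wref]
    return event_regressor(events, sample_times_s, hrf)


def estimate_bold(
    series: LinewidthSeries,
    regressor: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    min_valid: int = 10,
) -> BoldEstimate:
    """OLS of the cleaned linewidth on the BOLD model plus covariates.

    Default covariates are an intercept and a linear drift term; motion terms
    may be appended by the caller. ``delta_fwhm_hz`` is the negated regressor
    coefficient (activation narrows the line).
    """
    if len(regressor) != len(series):
        raise ValueError("regressor must be sampled at the series' onsets")
    v = series.valid
    y = series.fwhm_hz[v]
    t = series.onset_s[v]
    drift = (t - t.mean()) / max(t.std(), 1e-12)
    cols = [regressor[v], drift]
    names = ["bold", "drift"]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(series):
            cov = cov.T
        for j in range(cov.shape[1]):
            c = cov[v, j]
            if c.std() > 1e-12:
                cols.append((c - c.mean()) / c.std())
                names.append(covariate_names[j] if covariate_names else f"cov{j}")
    X = sm.add_constant(np.column_stack(cols))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient BOLD design (rank {rank} < {X.shape[1]}): "
            f"columns const,{','.join(names)}"
        )
    fit = sm.OLS(y, X).fit()
    coef, se, tval = fit.params[1], fit.bse[1], fit.tvalues[1]
    return BoldEstimate(
        delta_fwhm_hz=float(-coef),
        se=float(se),
        tstat=float(tval),
        n_used=int(v.sum()),
        reliable=bool(v.sum() >= min_valid),
    )
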
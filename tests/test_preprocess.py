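"""Registration, T_S-A binning, condition GLM and reference deconvolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmrspipe import SubjectTruth, build_schedule, simulate_transients
from fmrspipe.preprocess import (
    BIN_EDGES_S,
    RankDeficientDesignError,
    _solve_condition_glm,
    assign_bin,
    fit_condition_glm,
    reference_deconvolve,
    register_spectra,
)
from fmrspipe.quantify import fit_diff
from fmrspipe.spectra import Spectrum, fid_to_spectrum
from tests.conftest import CLEAN_TRUTH, REDUCED_DESIGN, REDUCED_PARAMS


class TestAssignBin:
    @pytest.mark.parametrize(
        "t_sa, expected",
        [
            (0.090, 0),
            (0.100, 1),  # lower limits inclusive
            (0.150, 1),
            (0.183, 2),
            (0.267, 3),
            (0.349, 3),
            (0.350, 4),
            (1.0, 4),
        ],
    )
    def test_examples(self, t_sa, expected):
        assert assign_bin(t_sa) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_bin(-0.01)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_consistent_with_edges(self, t):
        b = assign_bin(t)
        assert 0 <= b <= 4
        # bin index equals the count of edges at or below t
        assert b == int(np.sum(BIN_EDGES_S <= t))


def _single_resonance_fid(params, offset_hz, fwhm_hz, amp=10.0, phase_deg=0.0,
                          shape="lorentzian"):
    t = params.time_axis()
    if shape == "lorentzian":
        decay = np.exp(-math.pi * fwhm_hz * t)
    else:
        a = (math.pi * fwhm_hz) ** 2 / (4 * math.log(2))
        decay = np.exp(-a * t**2)
    return amp * decay * np.exp(2j * math.pi * offset_hz * t + 1j * np.deg2rad(phase_deg))


class TestRegistration:
    def test_recovers_analytic_frequency_shift(self, clean_series):
        fids = clean_series.fids.copy()
        sched = clean_series.schedule
        t = REDUCED_PARAMS.time_axis()
        sel = np.where(sched.is_metab & ~sched.edit_on)[0]
        target = sel[3]
        fids[target] = fids[target] * np.exp(2j * math.pi * 2.0 * t)
        shifted = clean_series.copy_with(fids=fids)
        _, est = register_spectra(shifted)
        assert est.freq_offset_hz[target] == pytest.approx(2.0, abs=0.05)

    def test_identity_gives_zero_estimates(self, clean_series):
        _, est = register_spectra(clean_series)
        sched = clean_series.schedule
        sel = sched.is_metab & ~sched.edit_on & ~sched.task_on
        assert np.abs(est.freq_offset_hz[sel]).max() < 0.02
        assert np.abs(est.phase_deg[sel]).max() < 0.5

    def test_recovers_analytic_phase_offset(self, clean_series):
        fids = clean_series.fids.copy()
        sched = clean_series.schedule
        sel = np.where(sched.is_metab & ~sched.edit_on)[0]
        target = sel[5]
        fids[target] = fids[target] * np.exp(1j * np.deg2rad(30.0))
        _, est = register_spectra(clean_series.copy_with(fids=fids))
        assert est.phase_deg[target] == pytest.approx(30.0, abs=1.0)

    def test_never_alters_amplitudes(self, noisy_series, registered_noisy):
        """Registration is a pure phase/frequency modulation: the pointwise
        magnitude of every FID is unchanged."""
        reg_ser, _ = registered_noisy
        np.testing.assert_allclose(
            np.abs(reg_ser.fids), np.abs(noisy_series.fids), atol=1e-9
        )

    def test_drift_correction_reduces_peak_position_scatter(self, reduced_schedule):
        """NAA peak-position SD across transients drops >= 90% after
        registration on a drifting, spike-free simulation."""
        truth = SubjectTruth(
            noise_sd=0.2, drift_hz_per_min=1.0, motion_spike_prob=0.0,
            fwhm_noise_sd_hz=0.0, bold_narrowing_hz=0.0,
        )
        ser = simulate_transients(reduced_schedule, truth, REDUCED_PARAMS, seed=31)
        reg_ser, _ = register_spectra(ser)

        def peak_pos_sd(fids, schedule):
            sel = np.where(schedule.is_metab & ~schedule.edit_on)[0]
            pos = []
            for i in sel:
                spec = fid_to_spectrum(fids[i], REDUCED_PARAMS)
                m = spec.region(1.8, 2.2)
                pos.append(spec.ppm_axis[m][np.argmax(spec.real[m])])
            return np.std(pos)

        from fmrspipe.preprocess import _unwind_phase_cycle

        # registered FIDs are already sign-unwound; raw ones are not
        sd_before = peak_pos_sd(_unwind_phase_cycle(ser), ser.schedule)
        sd_after = peak_pos_sd(reg_ser.fids, reg_ser.schedule)
        assert sd_after <= 0.1 * sd_before

    def test_all_zero_fid_marked_unusable(self, clean_series):
        fids = clean_series.fids.copy()
        fids[10] = 0.0
        _, est = register_spectra(clean_series.copy_with(fids=fids))
        assert not est.usable[10]
        assert est.usable.sum() == len(fids) - 1


class TestConditionGLM:
    def test_balanced_noiseless_equals_plain_means(self, clean_series):
        """With no nuisance variance the GLM reduces to per-condition means."""
        truth = SubjectTruth(**CLEAN_TRUTH, bold_narrowing_hz=0.0)
        ser = simulate_transients(
            clean_series.schedule, truth, REDUCED_PARAMS, seed=41
        )
        reg_ser, est = register_spectra(ser)
        cond = fit_condition_glm(reg_ser, est)
        sched = ser.schedule
        sel = sched.is_metab & ~sched.edit_on & ~sched.task_on
        mean_spec = fid_to_spectrum(reg_ser.fids[sel].mean(axis=0), REDUCED_PARAMS)
        np.testing.assert_allclose(
            cond.editoff["task_off"].values, mean_spec.values, atol=1e-8
        )

    def test_diff_of_identical_edit_states_is_zero(self, registered_noisy):
        """Forcing identical ON/OFF inputs yields an all-zero DIFF spectrum."""
        reg_ser, est = registered_noisy
        sched = reg_ser.schedule
        fids = reg_ser.fids.copy()
        # per condition label, give every metabolite transient (both edit
        # states) one identical representative FID
        from fmrspipe.preprocess import _condition_labels

        labels = _condition_labels(sched, "tsa_bins", None)
        for lab in np.unique(labels[sched.is_metab]):
            sel = np.where(sched.is_metab & (labels == lab))[0]
            fids[sel] = fids[sel[0]]
        cond = fit_condition_glm(reg_ser.copy_with(fids=fids), est)
        scale = np.abs(cond.editoff["task_off"].values).max()
        assert np.abs(cond.diff["task_off"].values).max() < 1e-6 * scale

    def test_outer_bins_absent_not_zero(self, registered_noisy):
        cond = fit_condition_glm(*registered_noisy)
        assert "bin0" not in cond.diff and "bin4" not in cond.diff
        assert cond.diff_bins[0] is None and cond.diff_bins[4] is None
        assert all(b is not None for b in cond.diff_bins[1:4])

    def test_condition_counts_conserve_metabolite_transients(self, registered_noisy):
        reg_ser, est = registered_noisy
        cond = fit_condition_glm(reg_ser, est)
        n_metab = int((reg_ser.schedule.is_metab & est.usable).sum())
        binned = sum(v for k, v in cond.counts.items() if k != "task_on")
        assert binned == n_metab
        assert cond.counts["task_on"] + cond.counts["task_off"] == n_metab

    def test_motion_regressors_reduce_spike_bias(self, reduced_schedule):
        """Paired run on a spike-contaminated simulation: the Glx amplitude
        error with motion regressors is below the error without them."""
        kw = dict(noise_sd=0.3, task_glx_frac=0.0, fwhm_noise_sd_hz=0.0)
        spiked = SubjectTruth(**kw, motion_spike_prob=0.15)
        clean = SubjectTruth(**kw, motion_spike_prob=0.0)
        # same seed: the noise stream is identical, so the spike-free run is
        # the exact reference for the spiked run's condition spectra
        ser_s = simulate_transients(reduced_schedule, spiked, REDUCED_PARAMS, seed=55)
        ser_c = simulate_transients(reduced_schedule, clean, REDUCED_PARAMS, seed=55)
        reg_c, est_c = register_spectra(ser_c)
        ref_area = fit_condition_glm(reg_c, est_c).diff["task_off"].area(3.45, 4.10)
        reg_s, est_s = register_spectra(ser_s)
        errs = {}
        for flag in (True, False):
            cond = fit_condition_glm(reg_s, est_s, motion_regressors=flag)
            errs[flag] = abs(cond.diff["task_off"].area(3.45, 4.10) - ref_area)
        assert errs[True] <= errs[False]

    def test_collinear_condition_columns_raise(self, registered_noisy):
        reg_ser, est = registered_noisy
        sched = reg_ser.schedule
        idx = np.where(sched.is_metab)[0]
        spectra = np.ones((idx.size, 4), dtype=complex)
        labels = np.array(["a"] * idx.size)
        with pytest.raises(RankDeficientDesignError):
            _solve_condition_glm(
                spectra, ["a", "a"], labels, np.zeros((idx.size, 1)), ["n"]
            )

    def test_stimulus_scheme_requires_trial_log(self, registered_noisy):
        reg_ser, est = registered_noisy
        ser = reg_ser.copy_with(trial_log=None)
        with pytest.raises(ValueError, match="trial log"):
            fit_condition_glm(ser, est, scheme="stimulus_and_accuracy")


class TestReferenceDeconvolution:
    def _spectrum(self, fid):
        return fid_to_spectrum(fid, REDUCED_PARAMS)

    def test_identity_when_ref_matches_ideal(self):
        """Gaussian target + reference with the same Gaussian envelope and
        matching ideal width: output equals input to machine precision."""
        p = REDUCED_PARAMS
        target = self._spectrum(
            _single_resonance_fid(p, -100.0, 6.0, shape="gaussian")
        )
        ref = self._spectrum(
            _single_resonance_fid(p, 0.0, 6.0, amp=1000.0, shape="gaussian")
        )
        out = reference_deconvolve(target, ref, 6.0, p)
        np.testing.assert_allclose(out.values, target.values, atol=1e-9)

    def test_lorentzian_to_gaussian_linewidth(self):
        """A 10 Hz Lorentzian deconvolved to a 6 Hz Gaussian target."""
        p = REDUCED_PARAMS
        target = self._spectrum(_single_resonance_fid(p, -150.0, 10.0))
        ref = self._spectrum(_single_resonance_fid(p, 0.0, 10.0, amp=1000.0))
        out = reference_deconvolve(target, ref, 6.0, p)
        m = out.region(2.0, 4.0)
        x, y = out.ppm_axis[m], out.real[m]
        from scipy.optimize import curve_fit

        def gauss(x, h, c, w, b):
            return h * np.exp(-4 * math.log(2) * ((x - c) / w) ** 2) + b

        popt, _ = curve_fit(gauss, x, y, p0=[y.max(), x[np.argmax(y)], 0.06, 0.0])
        assert popt[2] * p.f0_mhz == pytest.approx(6.0, abs=0.2)

    def test_noise_tail_gain_bounded(self):
        """The envelope floor caps amplification of the reference's noise
        tail at the documented 1/floor_frac bound."""
        p = REDUCED_PARAMS
        rng = np.random.default_rng(0)
        t = p.time_axis()
        fid = 1000.0 * np.exp(-math.pi * 8.0 * t)
        noise = 0.5 * (rng.standard_normal(p.n_points) + 1j * rng.standard_normal(p.n_points))
        ref = self._spectrum(fid + noise)
        target_fid = _single_resonance_fid(p, -150.0, 8.0) + noise
        target = self._spectrum(target_fid)
        out = reference_deconvolve(target, ref, 6.0, p, floor_frac=0.05)
        # compare late-FID (noise-dominated) energy before and after
        from fmrspipe.spectra import spectrum_to_fid

        tail_in = np.abs(spectrum_to_fid(target, p)[-200:])
        tail_out = np.abs(spectrum_to_fid(out, p)[-200:])
        assert tail_out.max() <= 20.0 * tail_in.max() + 1e-12

    def test_idempotent_once_applied(self):
        """Re-applying with the deconvolved reference changes FWHM < 1%."""
        p = REDUCED_PARAMS
        target = self._spectrum(_single_resonance_fid(p, -150.0, 10.0))
        ref = self._spectrum(_single_resonance_fid(p, 0.0, 10.0, amp=1000.0))
        once = reference_deconvolve(target, ref, 6.0, p)
        ref_once = reference_deconvolve(ref, ref, 6.0, p)
        twice = reference_deconvolve(once, ref_once, 6.0, p)

        def fwhm(spec):
            m = spec.region(2.0, 4.0)
            y = spec.real[m]
            half = y.max() / 2
            above = np.where(y >= half)[0]
            return (above[-1] - above[0]) * REDUCED_PARAMS.hz_per_point

        assert abs(fwhm(twice) - fwhm(once)) / fwhm(once) < 0.01

    def test_low_snr_reference_skipped_with_warning(self):
        p = REDUCED_PARAMS
        rng = np.random.default_rng(1)
        ref = self._spectrum(
            0.1 * (rng.standard_normal(p.n_points) + 1j * rng.standard_normal(p.n_points))
        )
        target = self._spectrum(_single_resonance_fid(p, -150.0, 10.0))
        with pytest.warns(UserWarning, match="deconvolution skipped"):
            out = reference_deconvolve(target, ref, 6.0, p)
        assert out.meta["deconvolved"] is False
        np.testing.assert_allclose(out.values, target.values)
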
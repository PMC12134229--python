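"""Synthetic interleaved GABA-edited fMRS data.

The generator is parametric, not quantum-mechanical: each transient is a sum
of damped complex exponentials at literature chemical shifts, with edit-state
dependent amplitudes chosen so the ON-OFF difference spectrum (DIFF) shows the
canonical MEGA-PRESS features — positive GABA+ at 3.01 ppm, a positive Glx
pseudo-doublet at 3.71/3.79 ppm, and an inverted NAA resonance at 2.01 ppm.
Task-ON transients carry a fractional Glx/GABA+ amplitude increase; the BOLD
response narrows every line through an HRF-convolved linewidth trace; drift,
2-step phase cycling (receiver sign alternation plus a sign-locked baseline
offset), motion spikes and complex Gaussian noise complete the contamination
model.

Edit-state amplitude factors (documented constants):

==========  ========  =====  =====
resonance   ppm       OFF    ON
==========  ========  =====  =====
NAA         2.01      1.0    0.5
Cr          3.03      1.0    1.0
Cho         3.20      1.0    1.0
Glx (x2)    3.71/3.79 0.5    1.0
GABA+       3.01      0.0    1.0
==========  ========  =====  =====

so DIFF areas are: GABA+ = gaba_plus/2, Glx = amp_glx/4, NAA = -amp_naa/4
(a resonance of time-domain amplitude A has absorption area A/2), with
``gaba_plus = amp_gaba / (1 - mm_fraction)`` honouring the co-edited
macromolecule share of the 3.0 ppm signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hrf import event_regressor
from .params import AcquisitionParams, ConfigurationError, HRFParams, TaskDesign
from .schedule import AcquisitionSchedule, build_schedule

__all__ = [
    "SubjectTruth",
    "TransientSeries",
    "CohortConfig",
    "simulate_transients",
    "simulate_behaviour",
    "simulate_cohort",
    "GLX_IU_PER_AMP",
]

#: i.u. produced per unit of truth Glx amplitude under the default water
#: amplitude (1000) and the documented water-scaling constant K = 2500:
#: iu = (amp_glx / 4) / (amp_water / 2) * K.
GLX_IU_PER_AMP = 1.25
GABA_IU_PER_AMP = 2.5  # per unit gaba_plus amplitude: (g/2)/(500) * 2500


@dataclass
class SubjectTruth:
    """Ground-truth generative parameters for one subject."""

    amp_gaba: float = 0.6
    amp_glx: float = 12.0
    amp_naa: float = 30.0
    amp_cr: float = 20.0
    amp_cho: float = 6.0
    amp_water: float = 1000.0
    mm_fraction: float = 0.5
    task_glx_frac: float = 0.06
    task_gaba_frac: float = 0.0
    early_bin_boost: float = 0.0
    bold_narrowing_hz: float = 0.5
    base_fwhm_hz: float = 8.0
    fwhm_noise_sd_hz: float = 0.15  # physiological (respiratory/cardiac) B0 jitter
    drift_hz_per_min: float = 0.5
    motion_spike_prob: float = 0.01
    noise_sd: float = 1.0
    pc_offset: complex = 0.5 + 0.0j
    residual_water_frac: float = 0.002
    fgm: float = 0.6
    age_y: float = 31.5
    group: str = "control"
    panss_p3: float = 0.0
    panss_pos: float = 0.0
    panss_neg: float = 0.0
    panss_total: float = 0.0
    ddd: float = 0.0
    is_active: bool = False

    def __post_init__(self) -> None:
        for name in ("amp_gaba", "amp_glx", "amp_naa", "amp_cr", "amp_cho", "amp_water"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        for name in ("task_glx_frac", "task_gaba_frac", "early_bin_boost"):
            v = getattr(self, name)
            if not np.isfinite(v) or not -0.5 < v < 0.5:
                raise ConfigurationError(f"{name} must lie in (-0.5, 0.5), got {v}")
        if not np.isfinite(self.bold_narrowing_hz) or self.bold_narrowing_hz < 0:
            raise ConfigurationError("bold_narrowing_hz must be finite and >= 0")
        if not 0 < self.fgm < 1:
            raise ConfigurationError(f"fgm must lie in (0, 1), got {self.fgm}")
        for name in ("base_fwhm_hz", "drift_hz_per_min", "noise_sd", "motion_spike_prob"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    @property
    def gaba_plus_amp(self) -> float:
        """GABA + co-edited macromolecule amplitude at 3.01 ppm (edit-ON)."""
        return self.amp_gaba / (1.0 - self.mm_fraction)

    def expected_diff_areas(self) -> dict[str, float]:
        """Noise-free task-OFF DIFF peak areas implied by the edit factors."""
        return {
            "gaba": self.gaba_plus_amp / 2.0,
            "glx": self.amp_glx / 4.0,
            "naa": -self.amp_naa / 4.0,
        }


# (ppm, amplitude attribute, OFF factor, ON factor)
_RESONANCES = [
    (2.01, "amp_naa", 1.0, 0.5),
    (3.03, "amp_cr", 1.0, 1.0),
    (3.20, "amp_cho", 1.0, 1.0),
    (3.71, "half_glx", 0.5, 1.0),
    (3.79, "half_glx", 0.5, 1.0),
    (3.01, "gaba_plus", 0.0, 1.0),
]


@dataclass
class TransientSeries:
    """Complex FIDs plus their acquisition schedule (and truth if simulated)."""

    fids: np.ndarray  # (n_transients, n_points) complex
    schedule: AcquisitionSchedule
    params: AcquisitionParams
    truth: SubjectTruth | None = None
    subject_id: str = "sim"
    hrf_trace: np.ndarray | None = None  # h(t) at transient onsets, peak 1
    motion_spikes: np.ndarray | None = None
    applied_freq_hz: np.ndarray | None = None
    applied_phase_deg: np.ndarray | None = None
    trial_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.fids = np.asarray(self.fids)
        if self.fids.ndim != 2 or self.fids.shape[0] != len(self.schedule):
            raise ValueError("fids must be (n_transients, n_points) matching schedule")
        if self.fids.shape[1] != self.params.n_points:
            raise ValueError("each FID must have params.n_points samples")

    def __len__(self) -> int:
        return self.fids.shape[0]

    def copy_with(self, **kw) -> "TransientSeries":
        d = dict(
            fids=self.fids,
            schedule=self.schedule,
            params=self.params,
            truth=self.truth,
            subject_id=self.subject_id,
            hrf_trace=self.hrf_trace,
            motion_spikes=self.motion_spikes,
            applied_freq_hz=self.applied_freq_hz,
            applied_phase_deg=self.applied_phase_deg,
            trial_log=self.trial_log,
        )
        d.update(kw)
        return TransientSeries(**d)


def _lorentzian_decay(t: np.ndarray, fwhm_hz: np.ndarray | float) -> np.ndarray:
    """exp(-pi * fwhm * t): Lorentzian absorption of the stated FWHM."""
    return np.exp(-math.pi * np.multiply.outer(np.asarray(fwhm_hz, float), t))


def simulate_transients(
    schedule: AcquisitionSchedule,
    truth: SubjectTruth,
    params: AcquisitionParams,
    seed: int,
    hrf: HRFParams | None = None,
) -> TransientSeries:
    """Synthesize the full interleaved transient series for one subject.

    Metabolite transients carry the edited resonance model; water-reference
    transients carry only the unsuppressed water line. The instantaneous
    linewidth of every resonance is ``base_fwhm_hz - bold_narrowing_hz * h``
    where h is the HRF-convolved trial-impulse regressor (peak normalised to 1)
    evaluated at each transient's onset.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    t = params.time_axis()
    tab = schedule.table
    onsets = schedule.onsets

    trial_times = schedule.trial_onsets()
    if trial_times.size:
        h = event_regressor(trial_times, onsets, hrf)
    else:
        h = np.zeros(n)
    fwhm = truth.base_fwhm_hz - truth.bold_narrowing_hz * h
    if truth.fwhm_noise_sd_hz > 0:
        fwhm = np.clip(fwhm + rng.normal(0.0, truth.fwhm_noise_sd_hz, n), 1.0, None)

    # per-transient frequency/phase errors: linear drift + motion spikes
    drift = truth.drift_hz_per_min * onsets / 60.0
    spikes = rng.random(n) < truth.motion_spike_prob
    spike_f = np.where(spikes, rng.normal(0.0, 5.0, n), 0.0)
    spike_p = np.where(spikes, rng.normal(0.0, 20.0, n), 0.0)
    # motion also causes partial signal dropout, which registration cannot
    # repair (that residual is what the spike nuisance regressor removes)
    spike_a = np.where(spikes, np.clip(rng.normal(1.0, 0.2, n), 0.4, 1.3), 1.0)
    freq_err = drift + spike_f
    phase_err_deg = spike_p

    is_wref = schedule.is_wref
    edit_on = schedule.edit_on
    task_on = schedule.task_on
    t_sa = tab["t_sa_s"].to_numpy(float)

    decay = _lorentzian_decay(t, fwhm)  # (n, n_points)
    fids = np.zeros((n, params.n_points), dtype=complex)

    # water-unsuppressed transients: water only, on carrier (0 Hz offset)
    fids[is_wref] = truth.amp_water * decay[is_wref]

    # metabolite transients
    glx_gain = np.ones(n)
    gaba_gain = np.ones(n)
    boost = np.where(np.nan_to_num(t_sa, nan=np.inf) < 0.183, truth.early_bin_boost, 0.0)
    glx_gain[task_on] = 1.0 + truth.task_glx_frac + boost[task_on]
    gaba_gain[task_on] = 1.0 + truth.task_gaba_frac

    metab = ~is_wref
    for ppm, attr, f_off, f_on in _RESONANCES:
        if attr == "half_glx":
            amp = truth.amp_glx / 2.0
            gain = glx_gain
        elif attr == "gaba_plus":
            amp = truth.gaba_plus_amp
            gain = gaba_gain
        else:
            amp = getattr(truth, attr)
            gain = np.ones(n)
        factor = np.where(edit_on, f_on, f_off)
        a = amp * factor * gain
        a[~metab] = 0.0
        if not np.any(a):
            continue
        carrier = np.exp(2j * math.pi * params.ppm_to_hz(ppm) * t)
        fids += (a[:, None] * decay) * carrier[None, :]
    if truth.residual_water_frac > 0:
        fids[metab] += truth.amp_water * truth.residual_water_frac * decay[metab]

    # drift / motion modulation (applies to all transients)
    mod = spike_a[:, None] * np.exp(
        2j * math.pi * freq_err[:, None] * t[None, :]
        + 1j * np.deg2rad(phase_err_deg)[:, None]
    )
    fids *= mod

    # 2-step phase cycle: receiver sign alternation on metabolite transients,
    # plus a small sign-locked baseline offset (survives the sign unwinding as
    # a phase-step-dependent nuisance for the condition GLM to remove)
    sign = np.where(metab, 1.0 - 2.0 * (tab["phase_step"].to_numpy() % 2), 1.0)
    fids *= sign[:, None]
    fids[metab] += truth.pc_offset

    if truth.noise_sd > 0:
        fids += truth.noise_sd * (
            rng.standard_normal(fids.shape) + 1j * rng.standard_normal(fids.shape)
        )

    return TransientSeries(
        fids=fids,
        schedule=schedule,
        params=params,
        truth=truth,
        hrf_trace=h,
        motion_spikes=spikes,
        applied_freq_hz=freq_err,
        applied_phase_deg=phase_err_deg,
    )


# --- behaviour ---------------------------------------------------------------

# Flanker performance model constants: right-skewed RTs (Gaussian + exponential
# tail) with a congruency penalty; patients respond slower, less accurately and
# miss more often, consistent with an executive/attentional deficit.
_RT_MU = {"control": 0.42, "patient": 0.45}
_RT_SIGMA = 0.05
_RT_TAU = 0.08
_RT_CONGRUENCY_PENALTY = 0.06
_ACC_CONGRUENT = {"control": 0.97, "patient": 0.89}
_ACC_INCONGRUENT_DROP = 0.07
_MISS_PROB = {"control": 0.02, "patient": 0.04}
_RT_MIN = 0.15


def simulate_behaviour(
    design: TaskDesign,
    subject: SubjectTruth,
    seed: int,
    session: str = "fMRS",
    congruency_penalty_s: float = _RT_CONGRUENCY_PENALTY,
) -> pd.DataFrame:
    """Simulate one session's trial log (trial_id, congruent, rt_s, correct)."""
    rng = np.random.default_rng(seed)
    n = design.n_trials
    congruent = rng.random(n) >= design.p_incongruent
    mu = _RT_MU.get(subject.group, _RT_MU["control"])
    rt = (
        mu
        + congruency_penalty_s * (~congruent)
        + rng.normal(0.0, _RT_SIGMA, n)
        + rng.exponential(_RT_TAU, n)
    )
    rt = np.clip(rt, _RT_MIN, design.response_window_s)
    p_base = _ACC_CONGRUENT.get(subject.group, _ACC_CONGRUENT["control"])
    p_correct = np.where(congruent, p_base, p_base - _ACC_INCONGRUENT_DROP)
    correct = rng.random(n) < p_correct
    missed = rng.random(n) < _MISS_PROB.get(subject.group, 0.02)
    correct[missed] = False
    rt[missed] = np.nan
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "congruent": congruent,
            "rt_s": rt,
            "correct": correct,
            "session": session,
        }
    )


# --- cohort ------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Statistical structure of a simulated case-control cohort.

    Effect sizes are stated in institutional units (i.u.) on the measured
    scale; truth amplitudes are derived via the documented i.u.-per-amplitude
    constants. Defaults describe the study cohort this package models: 51/51
    age-matched subjects, patients ~2.2 i.u. lower in baseline Glx, a ~6%
    task-locked Glx increase in both groups, and opposite-sign BOLD-Glx
    coupling (negative in controls, positive in patients).
    """

    n_control: int = 51
    n_patient: int = 51
    age_mean_y: float = 31.5
    age_sd_y: float = 9.1
    age_match_tol_y: float = 4.0
    glx_base_iu: float = 15.0
    glx_between_sd_iu: float = 1.0
    glx_group_offset_iu: float = -2.2
    glx_bold_slope_control: float = -0.38  # i.u. per fMRI Z unit
    glx_bold_slope_patient: float = 0.16
    gaba_base_iu: float = 3.0
    gaba_between_sd_iu: float = 0.4
    gaba_group_offset_iu: float = 0.0
    gaba_ddd_slope_iu: float = 0.147
    task_glx_frac: float = 0.06
    task_gaba_frac: float = 0.0
    # extra fractional Glx change for early (T_S-A < 183 ms) stimuli; off by
    # default so the pooled task-ON increase equals task_glx_frac exactly
    early_bin_boost: float = 0.0
    bold_mean_control_hz: float = 0.5
    bold_sd_control_hz: float = 0.15
    bold_mean_patient_hz: float = 0.35
    bold_sd_patient_hz: float = 0.25
    fmri_z_mean_control: float = 2.0
    fmri_z_sd_control: float = 0.8
    fmri_z_mean_patient: float = 1.5
    fmri_z_sd_patient: float = 1.0
    measurement_noise_iu: float = 0.3
    noise_sd: float = 1.0
    drift_hz_per_min: float = 0.5
    motion_spike_prob: float = 0.01
    sz_fraction: float = 36.0 / 51.0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_patient < 2:
            raise ConfigurationError("group sizes must be >= 2")


def simulate_cohort(
    config: CohortConfig,
    seed: int,
    params: AcquisitionParams | None = None,
    design: TaskDesign | None = None,
    make_transients: bool = True,
) -> tuple[list[TransientSeries], pd.DataFrame]:
    """Draw a cohort of subject truths, behaviour and (optionally) transients.

    Returns ``(series_list, table)``. The table always carries, besides truth
    parameters and covariates, directly simulated "measured" metabolite and
    BOLD columns (truth plus ``measurement_noise_iu`` Gaussian noise) so the
    statistical battery can be exercised without the spectral pipeline; a full
    pipeline run replaces these with spectroscopy-derived estimates.
    """
    params = params or AcquisitionParams()
    design = design or TaskDesign()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_c, n_p = config.n_control, config.n_patient
    n = n_c + n_p

    groups = ["control"] * n_c + ["patient"] * n_p
    ages_c = np.clip(rng.normal(config.age_mean_y, config.age_sd_y, n_c), 18, 65)
    ages_p = np.empty(n_p)
    for i in range(n_p):
        if i < n_c:  # pairwise age matching within the stated tolerance
            ages_p[i] = np.clip(
                ages_c[i] + rng.uniform(-config.age_match_tol_y, config.age_match_tol_y),
                18,
                67,
            )
        else:
            ages_p[i] = np.clip(rng.normal(config.age_mean_y, config.age_sd_y), 18, 65)
    ages = np.concatenate([ages_c, ages_p])
    is_patient = np.array([g == "patient" for g in groups])

    fgm = np.clip(rng.normal(0.55, 0.06, n), 0.30, 0.80)
    z = np.where(
        is_patient,
        rng.normal(config.fmri_z_mean_patient, config.fmri_z_sd_patient, n),
        rng.normal(config.fmri_z_mean_control, config.fmri_z_sd_control, n),
    )
    narrowing = np.where(
        is_patient,
        rng.normal(config.bold_mean_patient_hz, config.bold_sd_patient_hz, n),
        rng.normal(config.bold_mean_control_hz, config.bold_sd_control_hz, n),
    )
    # couple the fMRS narrowing to the fMRI Z so the two BOLD readouts correlate
    narrowing = np.clip(narrowing + 0.10 * (z - z.mean()), 0.05, None)

    z_centred = z - z.mean()
    slope = np.where(
        is_patient, config.glx_bold_slope_patient, config.glx_bold_slope_control
    )
    glx_iu_true = (
        config.glx_base_iu
        + config.glx_group_offset_iu * is_patient
        + slope * z_centred
        + rng.normal(0.0, config.glx_between_sd_iu, n)
    )
    glx_iu_true = np.clip(glx_iu_true, 1.0, None)

    ddd = np.where(is_patient, np.clip(rng.exponential(1.36, n), 0, 6), 0.0)
    ddd = np.where(is_patient & (rng.random(n) < 0.15), 0.0, ddd)  # some unmedicated
    is_active = ddd > 0
    gaba_iu_true = (
        config.gaba_base_iu
        + config.gaba_group_offset_iu * is_patient
        + config.gaba_ddd_slope_iu * ddd
        + rng.normal(0.0, config.gaba_between_sd_iu, n)
    )
    gaba_iu_true = np.clip(gaba_iu_true, 0.3, None)

    panss_p3 = np.where(is_patient, np.clip(np.round(rng.normal(4.6, 0.8, n)), 3, 7), 0)
    panss_pos = np.where(is_patient, np.clip(rng.normal(18.1, 5.2, n), 7, 40), 0)
    panss_neg = np.where(is_patient, np.clip(rng.normal(17.7, 7.4, n), 7, 40), 0)
    panss_total = np.where(is_patient, np.clip(rng.normal(69.7, 19.3, n), 30, 130), 0)
    subgroup = np.where(
        is_patient, np.where(rng.random(n) < config.sz_fraction, "SZ", "OD"), "none"
    )

    sub_seeds = rng.integers(0, 2**31 - 1, size=(n, 3))
    rows = []
    series_list: list[TransientSeries] = []
    meas = config.measurement_noise_iu
    for i in range(n):
        truth = SubjectTruth(
            amp_glx=glx_iu_true[i] / GLX_IU_PER_AMP,
            amp_gaba=(gaba_iu_true[i] / GABA_IU_PER_AMP) * 0.5,  # undo mm_fraction
            task_glx_frac=config.task_glx_frac,
            task_gaba_frac=config.task_gaba_frac,
            early_bin_boost=config.early_bin_boost,
            bold_narrowing_hz=float(narrowing[i]),
            noise_sd=config.noise_sd,
            drift_hz_per_min=config.drift_hz_per_min,
            motion_spike_prob=config.motion_spike_prob,
            fgm=float(fgm[i]),
            age_y=float(ages[i]),
            group=groups[i],
            panss_p3=float(panss_p3[i]),
            panss_pos=float(panss_pos[i]),
            panss_neg=float(panss_neg[i]),
            panss_total=float(panss_total[i]),
            ddd=float(ddd[i]),
            is_active=bool(is_active[i]),
        )
        sid = f"{'C' if groups[i] == 'control' else 'P'}{i:03d}"
        log = simulate_behaviour(design, truth, int(sub_seeds[i, 2]))
        if make_transients:
            sched = build_schedule(params, design, int(sub_seeds[i, 0]))
            series = simulate_transients(sched, truth, params, int(sub_seeds[i, 1]))
            series.subject_id = sid
            series.trial_log = log
            series_list.append(series)
        glx_on_true = glx_iu_true[i] * (1.0 + config.task_glx_frac)
        gaba_on_true = gaba_iu_true[i] * (1.0 + config.task_gaba_frac)
        rows.append(
            {
                "subject_id": sid,
                "group": groups[i],
                "subgroup": subgroup[i],
                "age_y": ages[i],
                "fgm": fgm[i],
                "panss_p3": panss_p3[i],
                "panss_pos": panss_pos[i],
                "panss_neg": panss_neg[i],
                "panss_total": panss_total[i],
                "ddd": ddd[i],
                "is_active": bool(is_active[i]),
                "bold_fmri_z": z[i],
                "bold_fmrs": narrowing[i] + rng.normal(0.0, 0.08),
                "truth_amp_glx": truth.amp_glx,
                "truth_amp_gaba": truth.amp_gaba,
                "truth_bold_narrowing_hz": truth.bold_narrowing_hz,
                "truth_glx_iu": glx_iu_true[i],
                "truth_gaba_iu": gaba_iu_true[i],
                "glx_off_iu": glx_iu_true[i] + rng.normal(0.0, meas),
                "glx_on_iu": glx_on_true + rng.normal(0.0, meas),
                "gaba_off_iu": gaba_iu_true[i] + rng.normal(0.0, meas),
                "gaba_on_iu": gaba_on_true + rng.normal(0.0, meas),
            }
        )
        metrics = _behaviour_summary(log)
        rows[-1].update(metrics)
    table = pd.DataFrame(rows)
    return series_list, table


def _behaviour_summary(log: pd.DataFrame) -> dict[str, float]:
    """Per-subject RA, median RT (correct trials), RA/RT and RT slowing."""
    ra = float(log["correct"].mean())
    ok = log[log["correct"] & log["rt_s"].notna()]
    rt = float(ok["rt_s"].median()) if len(ok) else np.nan
    rt_c = ok.loc[ok["congruent"], "rt_s"].median()
    rt_i = ok.loc[~ok["congruent"], "rt_s"].median()
    return {
        "ra": ra,
        "rt_s": rt,
        "ra_over_rt": ra / rt if rt and np.isfinite(rt) else np.nan,
        "rt_slowing_s": float(rt_i - rt_c) if np.isfinite(rt_i) and np.isfinite(rt_c) else np.nan,
    }
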
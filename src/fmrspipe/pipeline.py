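"""End-to-end orchestration: simulate -> preprocess -> quantify -> BOLD -> stats.

A :class:`RunConfig` pins every tunable (acquisition, design, cohort,
thresholds, stage toggles); :func:`run_subject` produces per-subject
artefacts and :func:`run_cohort` assembles the subject table, applies the
across-subject outlier stage, runs the statistical battery and writes a JSON
results manifest plus CSV tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bold as bold_mod
from . import quantify as qmod
from . import stats as smod
from .params import AcquisitionParams, ConfigurationError, HRFParams, TaskDesign
from .preprocess import (
    CONDITION_TASK_OFF,
    CONDITION_TASK_ON,
    ConditionSpectra,
    fit_condition_glm,
    reference_deconvolve,
    register_spectra,
)
from .simulate import CohortConfig, TransientSeries, simulate_cohort
from .spectra import fid_to_spectrum

log = logging.getLogger("fmrspipe")

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_cohort"]


@dataclass
class RunConfig:
    """Reproducible run description; round-trips through YAML unchanged."""

    seed: int = 0
    out_dir: str = "fmrspipe_out"
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    design: TaskDesign = field(default_factory=TaskDesign)
    hrf: HRFParams = field(default_factory=HRFParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ideal_fwhm_hz: float = 6.0
    gaba_fwhm_max_hz: float = 30.0
    naa_fwhm_max_hz: float = 12.0
    naa_snr_min: float = 20.0
    outlier_mad_factor: float = 5.0
    mixed_mad_factor: float = 2.5
    linewidth_mad_factor: float = 5.0
    jump_mad_factor: float = 3.0
    fit_conditions: tuple[str, ...] = ()  # empty = all available
    stages: tuple[str, ...] = ("simulate", "preprocess", "quantify", "bold", "stats")
    save_containers: bool = False

    def __post_init__(self) -> None:
        for nm in ("gaba_fwhm_max_hz", "naa_fwhm_max_hz", "naa_snr_min",
                   "outlier_mad_factor", "mixed_mad_factor", "ideal_fwhm_hz",
                   "linewidth_mad_factor", "jump_mad_factor"):
            if not getattr(self, nm) > 0:
                raise ConfigurationError(f"threshold {nm} must be positive")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "RunConfig":
        is_path = isinstance(src, Path) or (
            isinstance(src, str) and "\n" not in src and Path(src).exists()
        )
        text = Path(src).read_text() if is_path else str(src)
        d = yaml.safe_load(text)
        for key, sub in (
            ("acquisition", AcquisitionParams),
            ("design", TaskDesign),
            ("hrf", HRFParams),
            ("cohort", CohortConfig),
        ):
            if key in d and isinstance(d[key], dict):
                if key == "design" and "jitter_range_s" in d[key]:
                    d[key]["jitter_range_s"] = tuple(d[key]["jitter_range_s"])
                d[key] = sub(**d[key])
        for key in ("fit_conditions", "stages"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SubjectResult:
    subject_id: str
    estimates: list[qmod.MetaboliteEstimates]
    bold: bold_mod.BoldEstimate | None
    qc: dict[str, qmod.QCMetrics]
    condition_spectra: ConditionSpectra | None
    linewidths: bold_mod.LinewidthSeries | None
    timings: dict[str, float] = field(default_factory=dict)
    error: str = ""


def _matched_wref_spectrum(series: TransientSeries, task_on: bool):
    sched = series.schedule
    sel = sched.is_wref & (sched.task_on == task_on)
    if not sel.any():
        sel = sched.is_wref
    return fid_to_spectrum(series.fids[sel].mean(axis=0), series.params)


def run_subject(config: RunConfig, series: TransientSeries) -> SubjectResult:
    """Process one subject's transient series through the configured stages."""
    timings: dict[str, float] = {}
    sid = series.subject_id
    t0 = time.perf_counter()
    reg_series, reg_est = register_spectra(series)
    timings["register"] = time.perf_counter() - t0

    estimates: list[qmod.MetaboliteEstimates] = []
    qc: dict[str, qmod.QCMetrics] = {}
    cond = None
    if "quantify" in config.stages or "preprocess" in config.stages:
        t0 = time.perf_counter()
        cond = fit_condition_glm(reg_series, reg_est)
        timings["condition_glm"] = time.perf_counter() - t0
    if "quantify" in config.stages and cond is not None:
        t0 = time.perf_counter()
        ref_off = _matched_wref_spectrum(reg_series, task_on=False)
        ref_on = _matched_wref_spectrum(reg_series, task_on=True)
        water_area = ref_off.area(4.18, 5.18)
        wanted = config.fit_conditions or tuple(sorted(cond.diff.keys()))
        for cname in wanted:
            if cname not in cond.diff:
                continue
            ref = ref_off if cname == CONDITION_TASK_OFF else ref_on
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dspec = reference_deconvolve(
                    cond.diff[cname], ref, config.ideal_fwhm_hz, series.params
                )
            dfit = qmod.fit_diff(dspec)
            ofit = (
                qmod.fit_editoff(cond.editoff[cname])
                if cname in cond.editoff
                else None
            )
            est = qmod.scale_to_iu(
                dfit, water_area, subject_id=sid, condition=cname, editoff_fit=ofit
            )
            if dfit.converged:
                m0 = qmod.compute_qc(dfit, dspec)
                # re-classify under the configured thresholds
                m = qmod.classify_stage12(
                    m0.gaba_fwhm_hz, m0.naa_fwhm_hz, m0.naa_snr,
                    config.gaba_fwhm_max_hz, config.naa_fwhm_max_hz,
                    config.naa_snr_min,
                )
                qc[cname] = m
                est.reject_stage = m.reject_stage
                est.reject_reason = m.reject_reason
                est.usable = m.reject_stage == "none"
            estimates.append(est)
        timings["quantify"] = time.perf_counter() - t0

    bold_est = None
    lw = None
    if "bold" in config.stages:
        t0 = time.perf_counter()
        try:
            lw = bold_mod.linewidth_series(reg_series)
            lw = bold_mod.clean_series(
                lw,
                mad_factor=config.linewidth_mad_factor,
                jump_mad_factor=config.jump_mad_factor,
            )
            regressor = bold_mod.build_bold_regressor(series.schedule, config.hrf)
            bold_est = bold_mod.estimate_bold(lw, regressor)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("subject %s: BOLD stage failed: %s", sid, exc)
        timings["bold"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        log.info("subject %s: %s %.2fs", sid, stage, dt)
    return SubjectResult(
        subject_id=sid,
        estimates=estimates,
        bold=bold_est,
        qc=qc,
        condition_spectra=cond,
        linewidths=lw,
        timings=timings,
    )


def _estimates_frame(results: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for e in r.estimates:
            rows.append(dataclasses.asdict(e))
    return pd.DataFrame(rows)


def run_cohort(
    config: RunConfig,
    series_list: list[TransientSeries] | None = None,
    table: pd.DataFrame | None = None,
) -> dict:
    """Run the full cohort analysis; returns the results manifest (dict).

    If ``series_list``/``table`` are not supplied the cohort is simulated from
    ``config.cohort`` under ``config.seed``. Writes the estimates table, the
    subject table and ``manifest.json`` into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if series_list is None or table is None:
        if config.cohort.n_control + config.cohort.n_patient == 0:
            raise ConfigurationError("empty cohort")
        log.info("simulating cohort (%d+%d subjects)",
                 config.cohort.n_control, config.cohort.n_patient)
        series_list, table = simulate_cohort(
            config.cohort,
            config.seed,
            params=config.acquisition,
            design=config.design,
            make_transients="simulate" in config.stages,
        )
    table = table.copy().set_index("subject_id", drop=False)

    results: list[SubjectResult] = []
    for series in series_list:
        try:
            results.append(run_subject(config, series))
        except Exception as exc:  # keep the cohort running
            log.error("subject %s failed: %s", series.subject_id, exc)
            results.append(
                SubjectResult(series.subject_id, [], None, {}, None, None,
                              error=str(exc))
            )

    est_df = _estimates_frame(results)
    n_fitted = len(est_df)
    rejected_by_stage: dict[str, int] = {}
    if n_fitted:
        # stage 3: across-subject outlier rejection within each condition
        updated = []
        for cname, grp in est_df.groupby("condition"):
            ests = [
                qmod.MetaboliteEstimates(**{k: v for k, v in row.items()})
                for row in grp.to_dict("records")
            ]
            updated.extend(qmod.reject_outliers(ests, config.outlier_mad_factor))
        est_df = pd.DataFrame([dataclasses.asdict(e) for e in updated])
        rejected_by_stage = (
            est_df.loc[est_df.reject_stage != "none"]
            .groupby("reject_stage")
            .size()
            .to_dict()
        )
        est_df.to_csv(out / "estimates.csv", index=False)

        # merge pipeline-derived estimates into the subject table
        for cname, cols in (
            (CONDITION_TASK_OFF, ("glx_off_iu", "gaba_off_iu")),
            (CONDITION_TASK_ON, ("glx_on_iu", "gaba_on_iu")),
        ):
            sub = est_df[(est_df.condition == cname) & est_df.usable]
            sub = sub.set_index("subject_id")
            table.loc[sub.index, cols[0]] = sub["glx_iu"]
            table.loc[sub.index, cols[1]] = sub["gaba_iu"]
    for r in results:
        if r.bold is not None:
            table.loc[r.subject_id, "bold_fmrs"] = r.bold.delta_fwhm_hz
    table.to_csv(out / "subjects.csv", index=False)

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "n_subjects": len(table),
        "n_fitted_spectra": int(n_fitted),
        "n_usable": int(est_df["usable"].sum()) if n_fitted else 0,
        "rejected_by_stage": rejected_by_stage,
        "subject_errors": {r.subject_id: r.error for r in results if r.error},
        "models": {},
        "correlations": {},
        "behaviour": {},
    }

    if "stats" in config.stages:
        manifest.update(_cohort_stats(config, table))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("wrote %s", out / "manifest.json")
    return manifest


def _model_to_dict(res: smod.ModelResult) -> dict:
    return {
        "terms": [dataclasses.asdict(t) for t in res.terms],
        "n_used": res.n_used,
        "n_dropped": len(res.dropped),
        "diagnostics": res.diagnostics,
        "warnings": res.warnings,
    }


def _cohort_stats(config: RunConfig, table: pd.DataFrame) -> dict:
    models: dict = {}
    correlations: dict = {}
    behaviour: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for resp, label in (("glx_off_iu", "glx"), ("gaba_off_iu", "gaba")):
            for src in ("fmri", "fmrs"):
                try:
                    res = smod.fit_baseline_model(table, resp, src)
                    models[f"baseline_{label}_{src}"] = _model_to_dict(res)
                except (ValueError, KeyError) as exc:
                    models[f"baseline_{label}_{src}"] = {"error": str(exc)}
        for resp, label in (("glx", "glx"), ("gaba", "gaba")):
            try:
                long = _long_format(table, resp)
                res = smod.fit_mixed_model(
                    long, "value_iu", "task_state", config.mixed_mad_factor
                )
                d = _model_to_dict(res)
                try:
                    d["percent_task_effect"] = smod.percent_task_effect(res)
                except KeyError:
                    pass
                models[f"mixed_{label}_task"] = d
            except (ValueError, KeyError) as exc:
                models[f"mixed_{label}_task"] = {"error": str(exc)}
        try:
            models["medication_gaba"] = _model_to_dict(smod.medication_model(table))
        except ValueError as exc:
            models["medication_gaba"] = {"error": str(exc)}

        # BOLD cross-method correlation, per group and pooled
        for label, sub in (
            ("all", table),
            ("control", table[table.group == "control"]),
            ("patient", table[table.group == "patient"]),
        ):
            try:
                c = smod.skipped_spearman(
                    sub["bold_fmrs"], sub["bold_fmri_z"], seed=config.seed
                )
                d = dataclasses.asdict(c)
                d.pop("outlier_mask", None)
                correlations[f"bold_fmrs_vs_fmri_{label}"] = d
            except ValueError as exc:
                correlations[f"bold_fmrs_vs_fmri_{label}"] = {"error": str(exc)}
        ps = [
            v["p"] for v in correlations.values() if isinstance(v, dict) and "p" in v
            and np.isfinite(v["p"])
        ]
        if ps:
            adj = smod.holm_adjust(ps)
            i = 0
            for v in correlations.values():
                if isinstance(v, dict) and "p" in v and np.isfinite(v["p"]):
                    v["p_holm"] = float(adj[i])
                    i += 1

        # behavioural group contrasts (Mann-Whitney), Holm-adjusted as a family
        pvals, names = [], []
        for metric in ("ra", "rt_s", "ra_over_rt", "rt_slowing_s"):
            if metric not in table.columns:
                continue
            a = table.loc[table.group == "control", metric].dropna()
            b = table.loc[table.group == "patient", metric].dropna()
            if len(a) >= 2 and len(b) >= 2:
                stat, p = smod.rank_tests(a, b, paired=False)
                behaviour[metric] = {"U": stat, "p": p,
                                     "median_control": float(a.median()),
                                     "median_patient": float(b.median())}
                pvals.append(p)
                names.append(metric)
        if pvals:
            adj = smod.holm_adjust(pvals)
            for nm, ph in zip(names, adj):
                behaviour[nm]["p_holm"] = float(ph)
    return {"models": models, "correlations": correlations, "behaviour": behaviour}


def _long_format(table: pd.DataFrame, metab: str) -> pd.DataFrame:
    rows = []
    for _, r in table.iterrows():
        for state, col in (("OFF", f"{metab}_off_iu"), ("ON", f"{metab}_on_iu")):
            if col in r and np.isfinite(r[col]):
                rows.append(
                    {
                        "subject_id": r["subject_id"],
                        "group": r["group"],
                        "task_state": state,
                        "value_iu": r[col],
                        "fgm": r["fgm"],
                        "age_y": r["age_y"],
                    }
                )
    return pd.DataFrame(rows)
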
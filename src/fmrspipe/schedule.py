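"""Per-transient acquisition schedule for the interleaved edited sequence.

The schedule assigns, for each of the ``n_transients`` TRs: the water-reference
interleave (0-based indices 2, 5, 8, ...), the edit state (ON/OFF alternating
over the remaining metabolite transients), the 2-step phase cycle, the task
block state, and — for task-ON transients — the trial and its jittered
stimulus-to-acquisition interval T_S-A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AcquisitionParams, ConfigurationError, TaskDesign

__all__ = ["AcquisitionSchedule", "build_schedule"]

_COLUMNS = [
    "index",
    "onset_s",
    "edit_state",
    "is_wref",
    "phase_step",
    "task_state",
    "block_id",
    "trial_id",
    "t_sa_s",
    "stim_time_s",
]


@dataclass
class AcquisitionSchedule:
    """Table of per-transient metadata (one row per TR)."""

    table: pd.DataFrame
    params: AcquisitionParams
    design: TaskDesign

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"schedule table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_wref(self) -> np.ndarray:
        return self.table["is_wref"].to_numpy(bool)

    @property
    def is_metab(self) -> np.ndarray:
        return ~self.is_wref

    @property
    def edit_on(self) -> np.ndarray:
        return (self.table["edit_state"] == "ON").to_numpy()

    @property
    def task_on(self) -> np.ndarray:
        return (self.table["task_state"] == "ON").to_numpy()

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset_s"].to_numpy(float)

    def trial_onsets(self) -> np.ndarray:
        """Stimulus presentation times of all trials, in seconds."""
        t = self.table.loc[self.table["trial_id"].notna(), "stim_time_s"]
        return t.to_numpy(float)

    def counts(self) -> dict[str, int]:
        return {
            "n_transients": len(self),
            "n_wref": int(self.is_wref.sum()),
            "n_metab": int(self.is_metab.sum()),
            "n_task_on": int(self.task_on.sum()),
            "n_trials": int(self.table["trial_id"].notna().sum()),
            "n_task_off_metab": int((self.is_metab & ~self.task_on).sum()),
            "n_task_on_metab": int((self.is_metab & self.task_on).sum()),
        }


def build_schedule(
    params: AcquisitionParams, design: TaskDesign, seed: int
) -> AcquisitionSchedule:
    """Lay out the block-event task over the transient train.

    Water-reference flags are placed at 0-based indices 2, 5, 8, ...; edit
    state alternates ON/OFF over the remaining metabolite transients, and the
    2-step phase cycle advances once per completed ON/OFF pair. Every task-ON
    transient hosts one trial whose stimulus precedes the excitation pulse by
    T_S-A drawn uniformly from ``design.jitter_range_s``.
    """
    n_design = int(round(design.total_duration_s / params.tr_s))
    if n_design != params.n_transients:
        raise ConfigurationError(
            f"task design spans {n_design} transients "
            f"(total_duration_s={design.total_duration_s}, tr_s={params.tr_s}) "
            f"but params.n_transients={params.n_transients}"
        )
    rng = np.random.default_rng(seed)
    n = params.n_transients
    idx = np.arange(n)
    onset = idx * params.tr_s
    is_wref = (idx % params.wref_every) == (params.wref_every - 1)

    # edit state and phase cycle over metabolite transients
    edit_state = np.full(n, "OFF", dtype=object)
    phase_step = np.zeros(n, dtype=int)
    metab_idx = idx[~is_wref]
    edit_state[metab_idx[::2]] = "ON"
    phase_step[metab_idx] = (np.arange(metab_idx.size) // 2) % params.phase_cycle_steps
    wref_idx = idx[is_wref]
    phase_step[wref_idx] = np.arange(wref_idx.size) % params.phase_cycle_steps

    # task blocks
    task_state = np.full(n, "OFF", dtype=object)
    block_id = np.zeros(n, dtype=int)
    bounds = [0.0, design.initial_off_s]
    for _ in range(design.n_on_blocks):
        bounds.append(bounds[-1] + design.on_block_s)
        bounds.append(bounds[-1] + design.off_block_s)
    bounds_arr = np.asarray(bounds)
    block_id = np.searchsorted(bounds_arr[1:-1], onset, side="right")
    task_state[block_id % 2 == 1] = "ON"

    # one trial per task-ON TR; stimulus T_S-A before the excitation pulse
    trial_id = np.full(n, np.nan)
    t_sa = np.full(n, np.nan)
    stim_time = np.full(n, np.nan)
    on_idx = idx[task_state == "ON"]
    lo, hi = design.jitter_range_s
    jit = rng.uniform(lo, hi, size=on_idx.size)
    trial_id[on_idx] = np.arange(on_idx.size)
    t_sa[on_idx] = jit
    stim_time[on_idx] = onset[on_idx] - jit

    table = pd.DataFrame(
        {
            "index": idx,
            "onset_s": onset,
            "edit_state": edit_state,
            "is_wref": is_wref,
            "phase_step": phase_step,
            "task_state": task_state,
            "block_id": block_id,
            "trial_id": pd.array(trial_id, dtype="Int64"),
            "t_sa_s": t_sa,
            "stim_time_s": stim_time,
        }
    )
    return AcquisitionSchedule(table=table, params=params, design=design)
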
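"""HDF5 container and table I/O.

Layout of the transient container (one file per subject):

* ``/fids`` — complex128 dataset, shape (n_transients, n_points)
* ``/schedule/<column>`` — one dataset per schedule column
* ``/trial_log/<column>`` — optional behavioural log
* root attributes — acquisition params, design params, subject id, and
  (for simulated data) the ground-truth parameters prefixed ``truth_``
* ``/processed/<condition>`` — optional condition spectra (complex values
  plus a shared ppm axis)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .params import AcquisitionParams, TaskDesign
from .preprocess import ConditionSpectra
from .schedule import AcquisitionSchedule
from .simulate import SubjectTruth, TransientSeries
from .spectra import Spectrum

__all__ = ["save_series", "load_series", "save_condition_spectra", "load_condition_spectra"]

_SCHED_STR_COLS = {"edit_state", "task_state"}


def _write_df(grp: h5py.Group, df: pd.DataFrame) -> None:
    grp.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        v = df[col]
        if v.dtype == object or str(v.dtype) == "string":
            grp.create_dataset(col, data=np.array([str(x) for x in v], dtype="S"))
        elif str(v.dtype) == "Int64":
            grp.create_dataset(col, data=v.fillna(-1).to_numpy(np.int64))
        else:
            grp.create_dataset(col, data=v.to_numpy())


def _read_df(grp: h5py.Group) -> pd.DataFrame:
    out = {}
    for col in grp:
        arr = grp[col][()]
        if arr.dtype.kind == "S":
            out[col] = [x.decode() for x in arr]
        else:
            out[col] = arr
    df = pd.DataFrame(out)
    if "columns" in grp.attrs:
        df = df[json.loads(grp.attrs["columns"])]
    return df


def save_series(path: str | Path, series: TransientSeries) -> None:
    """Write a transient series (FIDs + schedule + params) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=series.fids)
        _write_df(f.create_group("schedule"), series.schedule.table)
        if series.trial_log is not None:
            _write_df(f.create_group("trial_log"), series.trial_log)
        f.attrs["subject_id"] = series.subject_id
        f.attrs["params"] = json.dumps(dataclasses.asdict(series.params))
        f.attrs["design"] = json.dumps(dataclasses.asdict(series.schedule.design))
        if series.truth is not None:
            d = dataclasses.asdict(series.truth)
            d["pc_offset"] = [series.truth.pc_offset.real, series.truth.pc_offset.imag]
            f.attrs["truth"] = json.dumps(d)


def load_series(path: str | Path) -> TransientSeries:
    """Read a transient series written by :func:`save_series`."""
    try:
        with h5py.File(path, "r") as f:
            fids = f["fids"][()]
            sched_df = _read_df(f["schedule"])
            params = AcquisitionParams(**json.loads(f.attrs["params"]))
            dd = json.loads(f.attrs["design"])
            dd["jitter_range_s"] = tuple(dd["jitter_range_s"])
            design = TaskDesign(**dd)
            truth = None
            if "truth" in f.attrs:
                td = json.loads(f.attrs["truth"])
                td["pc_offset"] = complex(*td["pc_offset"])
                truth = SubjectTruth(**td)
            trial_log = _read_df(f["trial_log"]) if "trial_log" in f else None
            subject_id = str(f.attrs.get("subject_id", "unknown"))
    except OSError as exc:
        raise IOError(f"cannot read transient container {path}: {exc}") from exc
    sched_df["trial_id"] = pd.array(sched_df["trial_id"], dtype="Int64")
    sched_df.loc[sched_df["trial_id"] < 0, "trial_id"] = pd.NA
    sched_df["is_wref"] = sched_df["is_wref"].astype(bool)
    schedule = AcquisitionSchedule(table=sched_df, params=params, design=design)
    return TransientSeries(
        fids=fids,
        schedule=schedule,
        params=params,
        truth=truth,
        subject_id=subject_id,
        trial_log=trial_log,
    )


def save_condition_spectra(path: str | Path, cond: ConditionSpectra) -> None:
    """Append condition spectra under /processed in an existing container."""
    with h5py.File(path, "a") as f:
        if "processed" in f:
            del f["processed"]
        grp = f.create_group("processed")
        first = next(iter(cond.diff.values()))
        grp.create_dataset("ppm_axis", data=first.ppm_axis)
        grp.attrs["f0_mhz"] = first.f0_mhz
        grp.attrs["counts"] = json.dumps(cond.counts)
        for sub, mapping in (("diff", cond.diff), ("editoff", cond.editoff),
                             ("editon", cond.editon)):
            g = grp.create_group(sub)
            for nm, spec in mapping.items():
                g.create_dataset(nm, data=spec.values)


def load_condition_spectra(path: str | Path) -> ConditionSpectra:
    with h5py.File(path, "r") as f:
        if "processed" not in f:
            raise IOError(f"{path} has no /processed group")
        grp = f["processed"]
        ppm = grp["ppm_axis"][()]
        f0 = float(grp.attrs["f0_mhz"])
        counts = json.loads(grp.attrs["counts"])
        params = AcquisitionParams(**json.loads(f.attrs["params"]))
        maps = {}
        for sub in ("diff", "editoff", "editon"):
            maps[sub] = {
                nm: Spectrum(grp[sub][nm][()], ppm.copy(), f0) for nm in grp[sub]
            }
    return ConditionSpectra(
        diff=maps["diff"], editoff=maps["editoff"], editon=maps["editon"],
        counts=counts, params=params,
    )
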
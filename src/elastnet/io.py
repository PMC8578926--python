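"""HDF5/CSV persistence for cohorts, datasets and reports."""

from __future__ import annotations

import json
from pathlib import PurePath
from typing import Optional

import h5py
import numpy as np

from .cohort import Cohort
from .preprocessing import ScalerState, SplitIndices

__all__ = [
    "save_simulation_hdf5",
    "save_cohort_hdf5",
    "load_cohort_waves",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
]


def save_simulation_hdf5(result, target, name: str = "simulation",
                         params: Optional[dict] = None) -> None:
    """Write one SimulationResult as an HDF5 group.

    ``target`` is a filename or an open h5py Group; the group holds
    time, per-site pressure and flow waves, the ventricular traces, and
    parameter/convergence attributes.
    """
    def write(group):
        n = result.lv_volume.size
        group.create_dataset("time", data=np.arange(n) * result.period / n)
        gp = group.create_group("pressure")
        for site, wave in result.pressure.items():
            gp.create_dataset(site, data=wave.samples)
        gf = group.create_group("flow")
        for site, q in result.flow.items():
            gf.create_dataset(site, data=q)
        group.create_dataset("lv_pressure", data=result.lv_pressure.samples)
        group.create_dataset("lv_volume", data=result.lv_volume)
        group.create_dataset("valve_flow", data=result.valve_flow)
        group.attrs["converged"] = result.converged
        group.attrs["cycles_run"] = result.cycles_run
        group.attrs["period"] = result.period
        if params:
            for k, v in params.items():
                group.attrs[f"param_{k}"] = v

    if isinstance(target, (str, PurePath)):
        with h5py.File(str(target), "a") as f:
            write(f.require_group(name))
    else:
        write(target.create_group(name))


def save_cohort_hdf5(cohort: Cohort, path: str, meta: Optional[dict] = None) -> None:
    """Waveform store: accepted subjects' brachial/aortic waves + targets."""
    waves_b, periods = cohort.waveform_matrix("brachial")
    waves_a, _ = cohort.waveform_matrix("aortic")
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["n_requested"] = cohort.n_requested
        f.attrs["n_accepted"] = cohort.n_accepted
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("brachial_pressure", data=waves_b)
        f.create_dataset("aortic_pressure", data=waves_a)
        f.create_dataset("period", data=periods)
        f.create_dataset("E_es_true", data=cohort.e_es_true())


def load_cohort_waves(path: str) -> dict[str, np.ndarray]:
    with h5py.File(path, "r") as f:
        return {
            "brachial_pressure": f["brachial_pressure"][:],
            "aortic_pressure": f["aortic_pressure"][:],
            "period": f["period"][:],
            "E_es_true": f["E_es_true"][:],
            "attrs": dict(f.attrs),
        }


def save_dataset_hdf5(
    path: str,
    X: np.ndarray,
    y: np.ndarray,
    split: SplitIndices,
    scalers: dict[str, ScalerState],
    seed: int,
    meta: Optional[dict] = None,
) -> None:
    """Normalized model inputs (n, C, 200), targets and split bookkeeping."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = seed
        if meta:
            f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("inputs", data=X)
        f.create_dataset("targets", data=y)
        g = f.create_group("split")
        g.attrs["seed"] = split.seed
        for name in ("train", "validation", "test"):
            g.create_dataset(name, data=getattr(split, name))
        s = f.create_group("scalers")
        for chan, st in scalers.items():
            gc = s.create_group(chan)
            gc.create_dataset("data_min", data=st.data_min)
            gc.create_dataset("data_max", data=st.data_max)


def load_dataset_hdf5(path: str):
    with h5py.File(path, "r") as f:
        X = f["inputs"][:]
        y = f["targets"][:]
        split = SplitIndices(
            train=f["split/train"][:],
            validation=f["split/validation"][:],
            test=f["split/test"][:],
            seed=int(f["split"].attrs["seed"]),
        )
        scalers = {
            chan: ScalerState(
                data_min=f[f"scalers/{chan}/data_min"][:],
                data_max=f[f"scalers/{chan}/data_max"][:],
            )
            for chan in f["scalers"]
        }
    return X, y, split, scalers
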
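"""HDF5 persistence for geometries, doses and plans.

Layout (geometry): ``/masks/<name>`` uint8 3-D, ``/spacing`` float triple,
``/meta`` attrs carrying seed and anatomy parameters.  Plans add
``/fluence``, ``/dose`` (float64 3-D), the protocol JSON as an attribute and
the per-loop state log as JSON.  Round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dose_engine import DoseDistribution
from .pbaio import Plan
from .phantom import PatientGeometry
from .protocol import _protocol_from_dict, _protocol_to_dict

__all__ = ["save_geometry", "load_geometry", "save_plan", "load_plan"]


def save_geometry(geometry: PatientGeometry, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("masks")
        for name, mask in geometry.masks.items():
            g.create_dataset(name, data=mask.astype(np.uint8), compression="gzip")
        f.create_dataset("spacing", data=np.asarray(geometry.spacing))
        meta = f.create_group("meta")
        meta.attrs["seed"] = geometry.seed
        meta.attrs["grid_shape"] = np.asarray(geometry.grid_shape)
        meta.attrs["anatomy_params"] = json.dumps(geometry.anatomy_params)


def load_geometry(path) -> PatientGeometry:
    with h5py.File(path, "r") as f:
        masks = {name: f["masks"][name][()].astype(bool) for name in f["masks"]}
        spacing = tuple(float(s) for s in f["spacing"][()])
        meta = f["meta"].attrs
        geo = PatientGeometry(
            grid_shape=tuple(int(n) for n in meta["grid_shape"]),
            spacing=spacing, masks=masks, seed=int(meta["seed"]),
            anatomy_params=json.loads(meta["anatomy_params"]))
    geo.validate()
    return geo


def save_plan(plan: Plan, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fluence", data=plan.fluence)
        f.create_dataset("dose", data=plan.dose.values, compression="gzip")
        f.attrs["protocol"] = json.dumps(_protocol_to_dict(plan.protocol))
        f.attrs["state_log"] = json.dumps(plan.state_log)
        f.attrs["seed"] = plan.seed


def load_plan(path) -> Plan:
    with h5py.File(path, "r") as f:
        return Plan(
            fluence=f["fluence"][()],
            dose=DoseDistribution(f["dose"][()]),
            protocol=_protocol_from_dict(json.loads(f.attrs["protocol"])),
            state_log=json.loads(f.attrs["state_log"]),
            seed=int(f.attrs["seed"]))
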
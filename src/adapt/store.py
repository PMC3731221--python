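"""HDF5 serialization of trajectory ensembles and CSV exports."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .trajectory import TrajectoryEnsemble

__all__ = ["save_ensemble", "load_ensemble_arrays", "export_quantity_csv"]

_MEMBER_FIELDS = ("params", "states", "fluxes", "outputs", "data_costs", "reg_costs")


def save_ensemble(path, ensemble: TrajectoryEnsemble) -> None:
    """Write an ensemble to an HDF5 file (members stacked per field)."""
    cfg = ensemble.config
    with h5py.File(path, "w") as f:
        f.attrs["model_name"] = ensemble.model.name
        f.attrs["n_members"] = len(ensemble)
        f.attrs["n_attempted"] = ensemble.n_attempted
        f.attrs["config_json"] = json.dumps(
            {k: v for k, v in cfg.__dict__.items() if not k.startswith("_")},
            default=lambda o: list(o) if isinstance(o, tuple) else str(o),
        )
        f.create_dataset("times", data=ensemble.times)
        for field in _MEMBER_FIELDS:
            f.create_dataset(
                field, data=np.stack([getattr(m, field) for m in ensemble.members])
            )
        f.create_dataset(
            "provenance_json",
            data=np.array(
                [json.dumps(m.provenance, default=str) for m in ensemble.members],
                dtype=h5py.string_dtype(),
            ),
        )


def load_ensemble_arrays(path) -> dict:
    """Read back the raw arrays and metadata of a stored ensemble."""
    out = {}
    with h5py.File(path, "r") as f:
        out["model_name"] = f.attrs["model_name"]
        out["n_attempted"] = int(f.attrs["n_attempted"])
        out["config"] = json.loads(f.attrs["config_json"])
        out["times"] = f["times"][()]
        for field in _MEMBER_FIELDS:
            out[field] = f[field][()]
        out["provenance"] = [json.loads(s) for s in f["provenance_json"].asstr()[()]]
    return out


def export_quantity_csv(path, ensemble: TrajectoryEnsemble, selector: str) -> None:
    """One quantity's trajectories: rows = members, columns = time grid."""
    mat = ensemble.quantity_matrix(selector)
    df = pd.DataFrame(
        mat, columns=pd.Index(np.round(ensemble.times, 10), name="time")
    )
    df.index.name = "member"
    df.to_csv(path)
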
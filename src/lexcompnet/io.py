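"""HDF5 checkpoints: weights, dimensions, segment boundaries and run metadata."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .grunet import WEIGHT_NAMES, GRUParams
from .representations import AggregateSpec


def save_checkpoint(
    path,
    params: GRUParams,
    spec: AggregateSpec,
    epoch: int = 0,
    config: dict | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        for name in WEIGHT_NAMES:
            g.create_dataset(name, data=getattr(params, name))
        f.attrs["input_dim"] = params.input_dim
        f.attrs["hidden_dim"] = params.hidden_dim
        f.attrs["sem_dim"] = spec.sem_dim
        f.attrs["vis_dim"] = spec.vis_dim
        f.attrs["lex_dim"] = spec.lex_dim
        f.attrs["epoch"] = epoch
        f.attrs["config"] = json.dumps(config or {})


def load_checkpoint(path) -> tuple[GRUParams, AggregateSpec, dict]:
    with h5py.File(path, "r") as f:
        weights = {name: np.array(f["weights"][name]) for name in WEIGHT_NAMES}
        spec = AggregateSpec(
            int(f.attrs["sem_dim"]), int(f.attrs["vis_dim"]), int(f.attrs["lex_dim"])
        )
        meta = {
            "epoch": int(f.attrs["epoch"]),
            "config": json.loads(f.attrs["config"]),
        }
    return GRUParams(**weights), spec, meta
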
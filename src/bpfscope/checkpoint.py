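"""Single-file checkpoints bundling design, network weights, config and
training history."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .design import BPFDesign
from .network import NetworkDescriptor, NetworkWeights
from .train import TrainHistory

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path: str | Path, design: BPFDesign,
                    weights: NetworkWeights,
                    history: TrainHistory | None = None,
                    config: RunConfig | None = None) -> None:
    path = Path(path)
    design_doc = {
        "binary_phases_rad": design.binary_phases.tolist(),
        "ring_edges_normalized": design.ring_edges.tolist(),
        "design_wavelength_um": design.design_wavelength,
    }
    desc = weights.descriptor
    desc_doc = {"depth": desc.depth, "base_channels": desc.base_channels,
                "in_channels": desc.in_channels,
                "input_size": desc.input_size}
    cfg_doc = None
    if config is not None:
        cfg_doc = {
            "optics": dataclasses.asdict(config.optics),
            "train": dataclasses.asdict(config.train),
            "eval": dataclasses.asdict(config.eval),
            "seed": config.seed,
        }
    hist_csv = history.to_frame().to_csv(index=False) if history else ""
    np.savez(
        path,
        __design__=json.dumps(design_doc),
        __descriptor__=json.dumps(desc_doc),
        __config__=json.dumps(cfg_doc),
        __history__=hist_csv,
        **weights.params,
    )


def load_checkpoint(path: str | Path):
    """Returns (design, weights, history_frame_or_None, config_dict_or_None)."""
    import io

    import pandas as pd

    reserved = {"__design__", "__descriptor__", "__config__", "__history__"}
    with np.load(Path(path), allow_pickle=False) as blob:
        design_doc = json.loads(str(blob["__design__"]))
        desc_doc = json.loads(str(blob["__descriptor__"]))
        cfg_doc = json.loads(str(blob["__config__"]))
        hist_csv = str(blob["__history__"])
        params = {k: blob[k] for k in blob.files if k not in reserved}
    design = BPFDesign(
        binary_phases=np.asarray(design_doc["binary_phases_rad"], float),
        ring_edges=np.asarray(design_doc["ring_edges_normalized"], float),
        design_wavelength=float(design_doc["design_wavelength_um"]),
    )
    weights = NetworkWeights(NetworkDescriptor(**desc_doc), params)
    history = pd.read_csv(io.StringIO(hist_csv)) if hist_csv.strip() else None
    return design, weights, history, cfg_doc
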
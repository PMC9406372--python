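"""Checkpoint and history persistence for spec-built models."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arch import ArchitectureSpec, build_from_spec
from .model import Sequential


def save_checkpoint(path: str | Path, spec: ArchitectureSpec,
                    model: Sequential) -> Path:
    """Serialize a spec-built model's architecture and weights (.npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"input_shape": list(spec.input_shape),
                       "layers": [list(l) for l in spec.layers],
                       "name": spec.name})
    weights = model.get_weights()
    np.savez(path, meta=np.array(meta),
             **{f"w{i}": w for i, w in enumerate(weights)})
    return path


def load_checkpoint(path: str | Path) -> tuple[ArchitectureSpec, Sequential]:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
    spec = ArchitectureSpec(tuple(meta["input_shape"]),
                            tuple(tuple(l) for l in meta["layers"]),
                            name=meta["name"])
    model = build_from_spec(spec)
    model.set_weights(weights)
    return spec, model


def save_history(path: str | Path, history: list[dict]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(history).to_csv(path, index=False)
    return path
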
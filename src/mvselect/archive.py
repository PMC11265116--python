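"""Serialization of fitted model state to a single ``.npz`` archive.

The archive carries everything test-time prediction needs: the stage-2
decoder weights and biases, the refit latent code Z', the training
standardization statistics, the selected feature names per view, and a JSON
echo of the run configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import MultiViewDataset, StandardizationState
from .decoder import DecoderParams, DecoderSpec
from .model import RefitModel, RefitResults


def save_refit(
    results: RefitResults,
    state: StandardizationState,
    selected_names: list[list[str]],
    path: str | Path,
    config_echo: dict | None = None,
) -> None:
    """Write a fitted stage-2 model and its preprocessing state to ``path``.

    The (standardized, selected) training views are included so test-time
    prediction can keep its nearest-neighbor initialization.
    """
    arrays: dict[str, np.ndarray] = {"Z": results.Z}
    for d, X in enumerate(results.model.dataset.views):
        arrays[f"train_view_{d}"] = X
    meta = {
        "n_views": len(results.decoders),
        "latent_dim": results.model.latent_dim,
        "selected_names": selected_names,
        "specs": [],
        "config": config_echo or {},
        "objective": results.objective,
    }
    for d, params in enumerate(results.decoders):
        spec = params.spec
        meta["specs"].append(
            {
                "latent_dim": spec.latent_dim,
                "output_dim": spec.output_dim,
                "depth": spec.depth,
                "hidden_width": spec.hidden_width,
                "activation": spec.activation,
                "output_activation": spec.output_activation,
            }
        )
        for l, (W, b) in enumerate(zip(params.weights, params.biases)):
            arrays[f"W_{d}_{l}"] = W
            arrays[f"b_{d}_{l}"] = b
        arrays[f"mean_{d}"] = state.means[d]
        arrays[f"std_{d}"] = state.stds[d]
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_refit(path: str | Path):
    """Read back an archive; returns (RefitResults, StandardizationState,
    selected feature names per view, config echo)."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        Z = z["Z"]
        decoders, means, stds = [], [], []
        for d, spec_d in enumerate(meta["specs"]):
            spec = DecoderSpec(**spec_d)
            weights = [z[f"W_{d}_{l}"] for l in range(spec.depth)]
            biases = [z[f"b_{d}_{l}"] for l in range(spec.depth)]
            params = DecoderParams(spec, weights, biases)
            params.check_shapes()
            decoders.append(params)
            means.append(z[f"mean_{d}"])
            stds.append(z[f"std_{d}"])
        train_views = [z[f"train_view_{d}"] for d in range(meta["n_views"])]
    state = StandardizationState(means, stds)
    names = meta["selected_names"]
    placeholder = MultiViewDataset(
        train_views,
        [f"s{i}" for i in range(Z.shape[0])],
        [list(fn) for fn in names],
    )
    model = RefitModel.__new__(RefitModel)
    model.dataset = placeholder
    model.latent_dim = meta["latent_dim"]
    model.specs = [p.spec for p in decoders]
    results = RefitResults(model, Z, decoders, [], float(meta["objective"]), 0)
    return results, state, names, meta["config"]
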
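"""Artifact serialization and deterministic seed substreams.

Networks and controllers go to JSON (matrices row-major); traces and tidy
results go to CSV.  Round-trips preserve full float precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np

from softmode.controller import Controller
from softmode.evolution import EvolutionTrace
from softmode.grn_dynamics import GeneNetwork

__all__ = [
    "FORMAT_VERSION",
    "substream",
    "substream_seed",
    "save_artifact",
    "load_artifact",
    "save_trace",
]

FORMAT_VERSION = 1


def substream_seed(global_seed: int, salt: str) -> np.random.SeedSequence:
    """Named substream: hashing the salt keeps streams stable when new
    stochastic components are added elsewhere."""
    digest = hashlib.blake2b(salt.encode(), digest_size=8).digest()
    return np.random.SeedSequence([int(global_seed), int.from_bytes(digest, "big")])


def substream(global_seed: int, salt: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(global_seed, salt))


def _network_payload(net: GeneNetwork) -> dict:
    return {
        "kind": "network",
        "version": FORMAT_VERSION,
        "n_genes": net.n_genes,
        "k_mat": net.k_mat.tolist(),
        "K_mat": net.K_mat.tolist(),
        "decay": net.decay.tolist(),
        "n_wt": None if net.n_wt is None else net.n_wt.tolist(),
    }


def _controller_payload(ctrl: Controller) -> dict:
    return {
        "kind": "controller",
        "version": FORMAT_VERSION,
        "k_channels": ctrl.k_channels,
        "sense_mat": ctrl.sense_mat.tolist(),
        "action_mat": ctrl.action_mat.tolist(),
        "c_p": ctrl.c_p,
        "c_i": ctrl.c_i,
    }


def save_artifact(obj: Union[GeneNetwork, Controller], path) -> None:
    path = Path(path)
    if isinstance(obj, GeneNetwork):
        payload = _network_payload(obj)
    elif isinstance(obj, Controller):
        payload = _controller_payload(obj)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    path.write_text(json.dumps(payload, indent=1))


def load_artifact(path) -> Union[GeneNetwork, Controller]:
    """Load and re-validate a serialized network or controller."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt artifact file {path}: {exc}") from exc
    kind = payload.get("kind")
    version = payload.get("version")
    if version != FORMAT_VERSION:
        warnings.warn(
            f"artifact version {version} != expected {FORMAT_VERSION}; loading anyway"
        )
    try:
        if kind == "network":
            return GeneNetwork(
                k_mat=np.array(payload["k_mat"], dtype=float),
                K_mat=np.array(payload["K_mat"], dtype=float),
                decay=np.array(payload["decay"], dtype=float),
                n_wt=None
                if payload.get("n_wt") is None
                else np.array(payload["n_wt"], dtype=float),
            )
        if kind == "controller":
            return Controller(
                sense_mat=np.array(payload["sense_mat"], dtype=float),
                action_mat=np.array(payload["action_mat"], dtype=float),
                c_p=float(payload["c_p"]),
                c_i=float(payload["c_i"]),
            )
    except KeyError as exc:
        raise ValueError(f"artifact {path} is missing field {exc}") from exc
    raise ValueError(f"artifact {path} has unknown kind {kind!r}")


def save_trace(trace: EvolutionTrace, path) -> None:
    """Trace CSV with columns step, cost, accepted, temperature, mode_gap."""
    trace.to_frame().to_csv(path, index=False)
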
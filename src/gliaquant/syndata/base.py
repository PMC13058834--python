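"""Common ground-truth container and deterministic RNG derivation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np


def object_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent RNG stream for one generated object.

    Streams are keyed by (seed, *key) through a SeedSequence spawn key, so
    adding later objects never reshuffles the draws of earlier ones.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _jsonable(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic dataset.

    ``modality`` tags which generator produced it; ``values`` maps names of
    generated observables (per-cell counts, transient times, true period,
    state sequence, ...) to their true values. Every observable a generator
    injects is recorded here, so any downstream recovery can be scored
    without re-deriving anything from the data.
    """

    modality: str
    values: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"modality": self.modality, "values": _jsonable(self.values)},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload
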
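"""Small shared helpers: canonical JSON, hashing, seeded RNG streams."""
from __future__ import annotations

import hashlib
import json

import numpy as np


def canonical_json(obj) -> str:
    """Serialize to a canonical JSON string (sorted keys, full float precision)."""
    return json.dumps(_jsonable(obj), sort_keys=True, separators=(",", ":"))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    return obj


def sha256_of_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stream_rng(seed: int, *tags: int) -> np.random.Generator:
    """Counter-based (Philox) generator for the sub-stream identified by tags.

    Every stochastic component of the package draws from its own tagged
    stream so that unrelated settings (stride, burn-in, recording) cannot
    shift the random sequence of another component.
    """
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), *map(int, tags)])))


def fmt_float(x: float) -> str:
    """Shortest decimal string that round-trips the float64 exactly."""
    return repr(float(x))
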
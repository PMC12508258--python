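"""Shared helpers: reproducible RNG handling and seed derivation."""

from __future__ import annotations

import numpy as np

# Stage offsets for deriving per-stage seeds from a single pipeline seed.
_STAGE_OFFSETS = {
    "field": 1,
    "staining": 2,
    "render": 3,
    "twoplex": 4,
    "calibration": 5,
    "control": 6,
    "cohort": 7,
}

_MOD = 2**31 - 1


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a Generator; integers seed a fresh PCG64, Generators pass through."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage seed from a pipeline-level seed by fixed offsets.

    Deterministic, collision-sparse and bounded below 2**31 so the result is
    usable anywhere a plain integer seed is expected.
    """
    off = _STAGE_OFFSETS.get(stage)
    if off is None:
        off = 100 + (sum(ord(c) for c in stage) % 997)
    return (int(master) * 1_000_003 + off * 8191 + index * 131) % _MOD
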
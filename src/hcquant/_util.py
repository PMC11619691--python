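"""Shared constants and seeding helpers."""

from __future__ import annotations

import zlib

import numpy as np

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.9872e-3


def kt(temperature: float) -> float:
    """Thermal energy RT in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream derived from a global seed and a stream label.

    Streams are keyed by a CRC32 of the label, so adding a new generator to
    the pipeline never perturbs the draws of an existing one.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
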
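"""Shared numerical helpers: reporting rounds and seed fan-out."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["round_half_away", "child_rng", "child_seed"]


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention used for reported tables).

    numpy's default rounds half to even, which disagrees with how the
    concentration tables are reported (e.g. 71.5 -> 72, 10.57 -> 11).
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Derive an independent seed stream for a named generator.

    A single study seed fans out to per-generator streams so each synthetic
    input can be regenerated on its own without replaying the others.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))


def child_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, name))
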
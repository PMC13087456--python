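"""Deterministic per-stream random generators.

One user-facing integer seed is expanded into independent named streams via
``numpy.random.SeedSequence`` spawn keys derived from a CRC32 of the stream
name. Adding a new named stream therefore never perturbs existing ones, and
identical (seed, name) pairs always yield identical generators.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng"]


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream under a global seed.

    Parameters
    ----------
    seed:
        Global integer seed (non-negative).
    name:
        Stable stream identifier, e.g. ``"variants.background"``.
    """
    if seed is None or int(seed) < 0:
        raise ValueError("seed must be a non-negative integer")
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
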
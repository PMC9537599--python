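"""Named random streams: every source of randomness derives from one root
seed plus a stream name, so whole runs replay exactly from a manifest."""

from __future__ import annotations

import zlib

import numpy as np


def stream_seed(root_seed: int, name: str) -> int:
    """Stable child seed (< 2**31) for a named stream."""
    h = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stream(root_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(stream_seed(root_seed, name))
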
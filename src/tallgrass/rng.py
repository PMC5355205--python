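"""Named random substreams derived from a single run-level seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named stage of a seeded run.

    Streams are derived from (seed, crc32(name)) so two stages never share
    state and any stage can be re-run in isolation.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
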
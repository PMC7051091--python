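"""Named random substreams.

All stochastic stages derive their generators from a single root seed plus a
stream name, so any stage can be re-run in isolation and still reproduce the
exact draws it made inside a full pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "check_seed"]


def check_seed(seed: object) -> int:
    """Validate that *seed* is a plain integer and return it as ``int``.

    Booleans and floats are rejected: a silent ``seed=1.0`` would defeat
    reproducibility bookkeeping in run manifests.
    """
    if isinstance(seed, bool) or not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {seed!r}")
    return int(seed)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named stream under the given root seed.

    The stream key is a CRC32 of the name, folded into a
    :class:`numpy.random.SeedSequence` together with the root seed; distinct
    names give statistically independent streams, and the same (seed, name)
    pair always yields identical draws.
    """
    seed = check_seed(seed)
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key]))
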
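"""Seed-stream management.

Every stochastic stage draws from its own named substream of a single root
seed, so that reruns with the same root seed are byte-identical and stages
can be re-run in isolation without perturbing each other.  Substreams are
derived with :class:`numpy.random.SeedSequence` keyed on a CRC32 hash of the
stage label.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for substream `label` of root `seed`.

    Deterministic: (seed, label) -> identical generator state, independent of
    call order across labels.
    """
    if seed is None:
        raise ValueError("seed must be an integer, not None")
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
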
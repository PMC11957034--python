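"""Seeding discipline: one named substream per stochastic component.

Each component derives its generator from the user seed plus a stable
label hash, so adding a stochastic stage never perturbs the draws of an
existing one, and results are reproducible across platforms.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for component `label` derived from `seed`."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))])
    )
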
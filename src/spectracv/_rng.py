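"""Named random sub-streams derived from one master seed.

Every stochastic component (phenotypes, spectra, herds, outliers, fold
partitions, hyperparameter draws) pulls its own generator from
``substream(seed, name)``, so each component is reproducible in isolation
and adding draws to one component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_seed"]


def stream_seed(seed: int, name: str) -> int:
    """Derive a 31-bit child seed from (master seed, component name)."""
    tag = zlib.crc32(name.encode("utf-8"))
    mix = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]).generate_state(1)[0]
    return int(mix) & 0x7FFFFFFF


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named component of a master seed."""
    return np.random.default_rng(stream_seed(seed, name))
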
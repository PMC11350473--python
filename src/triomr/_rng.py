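"""Named random substreams derived from one master seed.

Every stochastic component (haplotype panel, trio sampling, exposure GWAS,
outcome noise) draws from its own generator so that, e.g., changing the
number of simulated GWAS individuals never perturbs the trio genotypes.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["component_rng"]


def component_rng(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` under ``master_seed``.

    The substream key is a CRC32 of the component name, so streams are
    stable across runs and machines and distinct components are
    statistically independent (distinct SeedSequence spawn keys).
    """
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))
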
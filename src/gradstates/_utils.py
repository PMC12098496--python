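"""Shared numerical helpers: Fisher z, seed fan-out, logging."""
from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("gradstates")

#: correlations are clipped to +/-(1 - R_CLIP) before atanh so z stays finite
R_CLIP = 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising atanh transform with clipping at +/-(1 - 1e-7)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0 + R_CLIP, 1.0 - R_CLIP)
    return np.arctanh(r)


def derive_seed(master_seed: int, *stream: int) -> int:
    """Deterministically derive a sub-stream seed below 2**31 from a master seed.

    Every stochastic stage draws its own seed through this function so that
    subsets of a run (a single subject, a single stage) are reproducible from
    the master seed alone.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(s) for s in stream]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(master_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *stream))
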
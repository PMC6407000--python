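"""Deterministic seed fan-out.

One master seed drives every stochastic stage.  Child seeds are derived
through :class:`numpy.random.SeedSequence` from the master seed plus a
stable tuple of integer keys (stage tag, replicate index, ...), so that
parallel and serial execution, or re-running a single stage in isolation,
produce identical streams.
"""

from __future__ import annotations

import numpy as np

# stage tags (arbitrary but frozen)
TAG_SIMULATE = 11
TAG_CVFOLDS = 23
TAG_LOOCV = 31
TAG_PERM_OUTCOME = 47
TAG_PERM_MIRNA = 53


def child_seed(master: int, *keys: int) -> int:
    """A 31-bit child seed deterministically derived from (master, *keys)."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(master: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *keys))
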
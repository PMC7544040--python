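"""Deterministic child-seed derivation.

A single master seed spawns per-task child seeds through a counter-keyed
:class:`numpy.random.SeedSequence`, so any cell of a sweep can be re-run
in isolation and still reproduce the full sweep bit-for-bit.
"""

from __future__ import annotations

import numpy as np

_MASK31 = 0x7FFFFFFF


def spawn_seed(master: int, *key: int) -> int:
    """Derive a 31-bit child seed from a master seed and an integer key path."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & _MASK31)
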
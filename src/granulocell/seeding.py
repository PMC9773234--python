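"""Deterministic seed derivation.

All randomness in a run flows from one master seed through a counter-based
splitting rule (numpy ``SeedSequence``), so any sample can be reproduced in
isolation from its manifest entry.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, *path: int) -> int:
    """A child seed for the integer path ``path`` under ``master_seed``.

    Stable across runs and platforms; the result is a non-negative int below
    2**31 so it can feed any downstream generator.
    """
    ss = np.random.SeedSequence([int(master_seed)] + [int(p) for p in path])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
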
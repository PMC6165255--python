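"""Shared helpers: seed substreams and logging setup."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, purpose: str, index: int = 0) -> int:
    """Derive an independent 31-bit seed from a master seed.

    Every source of randomness (splitting, codebook clustering, SVM,
    synthesis, ...) draws from its own named substream so that changing
    one stage's consumption never perturbs another stage.
    """
    tag = zlib.crc32(purpose.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), tag, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))
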
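"""Deterministic named-stream sub-seed derivation.

Every random stage derives its own seed from (master seed, stage label) by
hashing, so inserting or removing a stage never perturbs the randomness of
the others.  Sub-seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib

import numpy as np


def subseed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(subseed(master_seed, stage))
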
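"""Stable per-stage seed derivation.

All randomness in the package flows from one user seed; each stage derives
its own stream by hashing the stage name, so adding a stage never perturbs
another stage's draws and results are reproducible across platforms.
"""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *labels: str) -> int:
    """Derive a 31-bit child seed from ``seed`` and one or more stage labels."""
    key = ":".join([str(int(seed)), *labels]).encode()
    digest = hashlib.blake2s(key).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
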
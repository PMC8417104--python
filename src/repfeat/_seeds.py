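"""Stable sub-seed derivation.

Every stochastic stage derives its seed from the master seed plus a string
context (sample id, cohort name, analysis name) via SHA-256, so that runs
are reproducible, per-sample downsampling seeds are stable regardless of
iteration order, and publicity comparisons stay symmetric.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(*parts: object) -> int:
    """Deterministic 31-bit seed from an ordered tuple of parts."""
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
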
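"""Deterministic seed derivation: one experiment seed, stable per-stage sub-seeds."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *tags: object) -> int:
    """Derive a sub-seed < 2**31 from a master seed and a tag path.

    Sub-seeds are stable across runs and platforms (SHA-256 of the textual
    tag path), so any stage or single trial can be re-simulated in isolation.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
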
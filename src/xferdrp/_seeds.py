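"""Stable seed derivation so adding one experiment never perturbs another."""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Map any tuple of hashable, printable parts to a seed in [0, 2^31)."""
    key = ":".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)
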
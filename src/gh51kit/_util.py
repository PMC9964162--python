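"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(base_seed: int, stage: str) -> int:
    """Derive a stage-local RNG seed from the single pipeline seed.

    Stable across runs and platforms: SHA-256 of ``"<stage>:<seed>"``
    truncated to 63 bits.
    """
    digest = hashlib.sha256(f"{stage}:{base_seed}".encode()).digest()
    return int.from_bytes(digest[:8], "big") >> 1


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
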
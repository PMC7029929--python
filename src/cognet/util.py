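"""Small shared helpers: seed derivation and deterministic ordering utilities."""

from __future__ import annotations

import zlib


def derive_seed(seed: int, label: str) -> int:
    """Derive a reproducible sub-seed from a master seed and a stage label.

    Stages of the pipeline (bootstrap per method, simulator, replicate
    streams...) each draw their own seed so that any stage can be re-run in
    isolation with the same randomness it saw inside the full run.  The
    derivation is a CRC32 hash of ``"<seed>:<label>"`` folded into the
    non-negative 31-bit range, so it is stable across platforms and Python
    versions (unlike ``hash``).
    """
    data = f"{int(seed)}:{label}".encode("utf-8")
    return zlib.crc32(data) & 0x7FFFFFFF


def first_appearance_order(values) -> list:
    """Distinct values in order of first appearance."""
    seen = set()
    out = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out
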
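"""Small shared helpers."""

from __future__ import annotations

import hashlib


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from one base seed.

    Hashing the stage name means any stage can be rerun in isolation with
    the same stream it saw inside a full pipeline run.
    """
    digest = hashlib.sha256(f"{int(base_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
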
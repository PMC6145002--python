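"""Deterministic child-seed derivation.

A single master seed fans out to every stochastic component (per species, per
algorithm, per GCM, per permutation block) through a stable hash of string
tags, so results do not depend on execution order and parallel schedules
cannot reorder random draws.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(master: int, *tags: object) -> int:
    """Derive a child seed < 2**31 from a master seed and a tag path.

    The same (master, tags) pair always yields the same child; distinct tag
    paths yield (with overwhelming probability) distinct children.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
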
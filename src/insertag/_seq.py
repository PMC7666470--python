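"""Small sequence utilities shared across the pipeline."""

from __future__ import annotations

import edlib

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def infix_align(query: str, text: str, max_dist: int = -1) -> dict:
    """Best alignment of ``query`` anywhere inside ``text`` (edit distance)."""
    return edlib.align(query, text, mode="HW", task="locations", k=max_dist)


def infix_identity(query: str, text: str) -> float:
    """Identity of the best infix placement of query in text, on query length."""
    if not query or not text:
        return 0.0
    res = edlib.align(query, text, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return max(0.0, 1.0 - d / len(query))


def global_identity(a: str, b: str) -> float:
    """Identity of a global alignment, normalized to the shorter sequence.

    The shorter sequence is aligned as an infix of the longer one so that a
    clean sub-/super-sequence pair scores 1.0.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return max(0.0, 1.0 - d / len(short))
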
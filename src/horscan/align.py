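"""Thin edlib wrappers shared across the package.

Identity and divergence are edit-distance based: matching columns divided by
total alignment columns (matches + mismatches + gaps), the standard
indel-tolerant definition.
"""

from __future__ import annotations

import re

import edlib

__all__ = ["revcomp", "cigar_columns", "global_divergence", "infix_hit"]

_RC = str.maketrans("ACGTN", "TGCAN")
_CIG = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def cigar_columns(cigar: str) -> tuple[int, int]:
    """Return (total alignment columns, matching columns) from an extended cigar."""
    cols = 0
    matches = 0
    for num, op in _CIG.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
    return cols, matches


def global_divergence(a: str, b: str) -> float:
    """Global-alignment edit distance divided by alignment length, in [0, 1]."""
    if not a or not b:
        raise ValueError("global_divergence requires non-empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    cols, matches = cigar_columns(res["cigar"])
    return (cols - matches) / cols


def infix_hit(query: str, target: str) -> tuple[int, int, float]:
    """Best semi-global placement of `query` inside `target`.

    Returns (start, end, identity) with 0-based half-open coordinates in
    `target`.  Identity is matching columns over total alignment columns.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    cols, matches = cigar_columns(res["cigar"])
    start, end_incl = res["locations"][0]
    if start is None:  # pragma: no cover - edlib quirk for empty targets
        start = 0
    return start, end_incl + 1, matches / cols
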
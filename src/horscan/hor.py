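"""HOR copy segmentation, canonical/variant classification, consensus and divergence.

Within an MD-line-segment region of period n, unit boundaries are fixed by
an anchor monomer type: the type that most frequently begins an exact
n-length cycle while recurring at exactly distance n (i.e. a once-per-unit
type).  Cutting at every anchor occurrence yields HOR copies; the canonical
unit is the most frequent complete n-mer type sequence, every other copy is
a variant labelled V<m> by its monomer count, as in the field's aligned HOR
schemes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .monomer_types import pairwise_divergence

__all__ = [
    "HORCopy",
    "HORFamily",
    "DivergenceStats",
    "pick_anchor_and_segment",
    "define_canonical",
    "classify_copies",
    "family_consensus",
    "divergence_stats",
]


@dataclass
class HORCopy:
    """One segmented HOR unit."""

    start_enum: int
    type_seq: list[int]
    monomer_seqs: list[str] = field(default_factory=list)
    label: str = ""
    col_map: Optional[list[Optional[int]]] = None  # monomer offset -> canonical position

    @property
    def m(self) -> int:
        return len(self.type_seq)

    @property
    def nt_seq(self) -> str:
        return "".join(self.monomer_seqs)


@dataclass
class HORFamily:
    period: int
    canonical_type_seq: list[int]
    copies: list[HORCopy]

    @property
    def cv_string(self) -> str:
        return "".join("C" if c.label == "C" else "V" for c in self.copies)

    @property
    def n_canonical(self) -> int:
        return sum(1 for c in self.copies if c.label == "C")

    @property
    def n_variant(self) -> int:
        return len(self.copies) - self.n_canonical

    @property
    def span(self) -> tuple[int, int]:
        return (self.copies[0].start_enum, self.copies[-1].start_enum + self.copies[-1].m - 1)


@dataclass
class DivergenceStats:
    per_copy: list[float]  # percent divergence of each canonical copy from the consensus
    n_canonical: int

    @property
    def mean_pct(self) -> float:
        return sum(self.per_copy) / len(self.per_copy) if self.per_copy else 0.0


def _next_same_type(type_seq: Sequence[int]) -> list[Optional[int]]:
    nxt: dict[int, int] = {}
    out: list[Optional[int]] = [None] * len(type_seq)
    for i in range(len(type_seq) - 1, -1, -1):
        out[i] = nxt.get(type_seq[i])
        nxt[type_seq[i]] = i
    return out


def pick_anchor_and_segment(
    type_seq: Sequence[int],
    segment: tuple[int, int],
    period: int,
    monomer_seqs: Sequence[str] | None = None,
    start_enum: int = 1,
) -> list[HORCopy]:
    """Cut an MD-segment region into HOR copies at anchor-type occurrences.

    `type_seq`/`monomer_seqs` cover the full enumeration starting at
    `start_enum`; `segment` is the (start, end) enumeration interval of the
    MD line segment at this `period`.  Partial units at the segment edges
    are dropped; a segment shorter than two periods yields no copies.
    """
    n = period
    i0 = segment[0] - start_enum
    i1 = segment[1] - start_enum
    if i1 - i0 + 1 < 2 * n:
        return []
    nxt = _next_same_type(type_seq)
    counts: Counter[int] = Counter()
    first_pos: dict[int, int] = {}
    upper = min(i1 + 1, len(type_seq) - 2 * n + 1)
    for i in range(i0, upper):
        if nxt[i] == i + n and list(type_seq[i : i + n]) == list(type_seq[i + n : i + 2 * n]):
            t = type_seq[i]
            counts[t] += 1
            first_pos.setdefault(t, i)
    if not counts:
        return []
    # A good anchor recurs once per unit even across structural variants; a
    # type sitting in a duplicated row recurs at sub-unit distances and
    # would cut inside variant copies.  Penalize candidates by the number
    # of consecutive recurrences shorter than half a unit, then prefer the
    # most frequent cycle-beginner, then the earliest.
    occ: dict[int, list[int]] = {}
    for i in range(i0, i1 + 1):
        if type_seq[i] in counts:
            occ.setdefault(type_seq[i], []).append(i)
    short: dict[int, int] = {
        t: sum(1 for a, b in zip(pos, pos[1:]) if b - a < (n + 1) // 2) for t, pos in occ.items()
    }
    # Then prefer the type whose occurrence count is closest to the
    # expected number of units (a type deleted in some variants merges
    # copies; one duplicated in some variants splits them), then the type
    # occurring earliest in the region, which pins the unit phase to the
    # first monomer of the first complete copy.
    est_units = max(1, round((i1 - i0 + 1) / n))
    anchor = max(
        counts,
        key=lambda t: (-short[t], -abs(len(occ[t]) - est_units), -occ[t][0], counts[t]),
    )
    cuts = [i for i in range(i0, i1 + 1) if type_seq[i] == anchor]
    copies: list[HORCopy] = []
    for a, b in zip(cuts, cuts[1:]):
        seqs = list(monomer_seqs[a:b]) if monomer_seqs is not None else []
        copies.append(HORCopy(start_enum=start_enum + a, type_seq=list(type_seq[a:b]), monomer_seqs=seqs))
    return copies


def define_canonical(copies: Sequence[HORCopy], period: int | None = None) -> list[int]:
    """The most frequent complete n-mer type sequence; ties to earliest occurrence."""
    if not copies:
        raise ValueError("define_canonical requires at least one copy")
    if period is None:
        lengths = Counter(c.m for c in copies)
        period = max(lengths, key=lambda m: (lengths[m], -m))
    pool = [c for c in copies if c.m == period] or list(copies)
    counts: Counter[tuple[int, ...]] = Counter(tuple(c.type_seq) for c in pool)
    first: dict[tuple[int, ...], int] = {}
    for idx, c in enumerate(pool):
        first.setdefault(tuple(c.type_seq), idx)
    best = max(counts, key=lambda s: (counts[s], -first[s]))
    return list(best)


def _align_type_seqs(copy_seq: Sequence[int], canon: Sequence[int]) -> list[Optional[int]]:
    """Monomer-level alignment of a copy's type sequence to the canonical unit.

    Unit-cost edit alignment over type ids; returns, per copy position, the
    aligned canonical position (None for inserted monomers).
    """
    m, n = len(copy_seq), len(canon)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        dp[i][0] = i
    for j in range(n + 1):
        dp[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = dp[i - 1][j - 1] + (copy_seq[i - 1] != canon[j - 1])
            dp[i][j] = min(sub, dp[i - 1][j] + 1, dp[i][j - 1] + 1)
    col_map: list[Optional[int]] = [None] * m
    i, j = m, n
    while i > 0 and j > 0:
        if dp[i][j] == dp[i - 1][j - 1] + (copy_seq[i - 1] != canon[j - 1]):
            col_map[i - 1] = j - 1
            i, j = i - 1, j - 1
        elif dp[i][j] == dp[i - 1][j] + 1:
            i -= 1
        else:
            j -= 1
    return col_map


def classify_copies(copies: Sequence[HORCopy], canonical_type_seq: Sequence[int]) -> HORFamily:
    """Label each copy C (exact canonical type sequence) or V<m>, build the family."""
    canon = list(canonical_type_seq)
    labelled: list[HORCopy] = []
    for c in copies:
        is_c = c.type_seq == canon
        label = "C" if is_c else f"V{c.m}"
        col_map = list(range(len(canon))) if is_c else _align_type_seqs(c.type_seq, canon)
        labelled.append(
            HORCopy(
                start_enum=c.start_enum,
                type_seq=list(c.type_seq),
                monomer_seqs=list(c.monomer_seqs),
                label=label,
                col_map=col_map,
            )
        )
    return HORFamily(period=len(canon), canonical_type_seq=canon, copies=labelled)


def _column_consensus(seqs: Sequence[str], ref: str) -> str:
    """Majority base per reference column over sequences aligned to `ref`.

    Substitution votes are collected through global alignment of each
    sequence to the reference; ties between bases break alphabetically; a
    column is dropped only when deletions hold a strict majority.
    Insertions relative to the reference do not vote.
    """
    votes: list[Counter[str]] = [Counter() for _ in range(len(ref))]
    for s in seqs:
        if s == ref:
            for j, b in enumerate(ref):
                votes[j][b] += 1
            continue
        res = edlib.align(s, ref, mode="NW", task="path")
        i = j = 0
        for num, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
            k = int(num)
            if op in "=X":
                for _ in range(k):
                    votes[j][s[i]] += 1
                    i += 1
                    j += 1
            elif op == "I":  # present in s, absent in ref: no column to vote in
                i += k
            elif op == "D":  # deleted in s
                for _ in range(k):
                    votes[j]["-"] += 1
                    j += 1
    out = []
    for v in votes:
        base_votes = [(cnt, b) for b, cnt in v.items() if b != "-"]
        if not base_votes:
            continue
        best_cnt = max(cnt for cnt, _ in base_votes)
        best = min(b for cnt, b in base_votes if cnt == best_cnt)
        if v.get("-", 0) > best_cnt:
            continue
        out.append(best)
    return "".join(out)


def family_consensus(canonical_copies: Sequence[HORCopy], centroids: dict[int, str] | None = None) -> str:
    """Consensus nucleotide sequence of the canonical unit.

    Canonical copies share the same type sequence, so monomers align
    position-by-position; within a monomer position, columns come from
    global alignment of every copy's monomer to the position's modal
    monomer sequence (an atypical reference, e.g. a boundary-trimmed one,
    would systematically drop or shift columns) and the majority base wins,
    ties alphabetical.  `centroids` is the fallback reference for positions
    where every observed monomer is unique.
    """
    if not canonical_copies:
        raise ValueError("family_consensus requires at least one canonical copy")
    unit_len = canonical_copies[0].m
    type_seq = canonical_copies[0].type_seq
    parts = []
    for j in range(unit_len):
        seqs = [c.monomer_seqs[j] for c in canonical_copies]
        counts = Counter(seqs)
        top = max(counts.values())
        if top > 1:
            ref = min(s for s, n in counts.items() if n == top)
        else:
            ref = (centroids or {}).get(type_seq[j]) or _modal_length_ref(seqs)
        parts.append(_column_consensus(seqs, ref))
    return "".join(parts)


def _modal_length_ref(seqs: Sequence[str]) -> str:
    lengths = Counter(len(s) for s in seqs)
    mode_len = max(lengths, key=lambda L: (lengths[L], L))
    return min(s for s in seqs if len(s) == mode_len)


def divergence_stats(canonical_copies: Sequence[HORCopy], consensus: str) -> DivergenceStats:
    """Percent divergence of each canonical copy's nucleotide sequence from the consensus."""
    per_copy = [100.0 * pairwise_divergence(c.nt_seq, consensus) for c in canonical_copies]
    return DivergenceStats(per_copy=per_copy, n_canonical=len(per_copy))
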
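"""MD diagram and GRM period-frequency computation.

An MD-point (l, p) marks the monomer with enumeration l whose next
same-type monomer sits exactly p positions downstream, with no intervening
occurrence of that type.  The GRM diagram is the per-period frequency of
MD-points; a tandem HOR of period n shows up as a dominant horizontal MD
line segment at n and a matching GRM peak.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "MDPoint",
    "PeriodHistogram",
    "md_points",
    "period_histogram",
    "md_line_segments",
    "frequency_table",
]

DEFAULT_MAX_PERIOD = 90


@dataclass(frozen=True)
class MDPoint:
    enumeration: int  # 1-based monomer index
    period: int


@dataclass
class PeriodHistogram:
    freq: dict[int, int]
    max_period: int = DEFAULT_MAX_PERIOD

    def __getitem__(self, period: int) -> int:
        return self.freq.get(period, 0)

    @property
    def total(self) -> int:
        return sum(self.freq.values())

    def argmax(self) -> int | None:
        """Most frequent period; ties broken toward the larger period."""
        if not self.freq:
            return None
        return max(self.freq, key=lambda p: (self.freq[p], p))


def md_points(type_seq: Sequence[int], max_period: int = DEFAULT_MAX_PERIOD, start_enum: int = 1) -> list[MDPoint]:
    """One MD-point per monomer whose next same-type occurrence is within `max_period`."""
    nxt: dict[int, int] = {}
    points: list[MDPoint] = []
    for i in range(len(type_seq) - 1, -1, -1):
        t = type_seq[i]
        j = nxt.get(t)
        if j is not None and j - i <= max_period:
            points.append(MDPoint(enumeration=start_enum + i, period=j - i))
        nxt[t] = i
    points.reverse()
    return points


def period_histogram(points: Sequence[MDPoint], max_period: int = DEFAULT_MAX_PERIOD) -> PeriodHistogram:
    return PeriodHistogram(freq=dict(Counter(p.period for p in points)), max_period=max_period)


def md_line_segments(
    points: Sequence[MDPoint],
    period: int,
    min_run: int = 20,
    min_density: float = 0.5,
) -> list[tuple[int, int]]:
    """Maximal enumeration intervals dense in MD-points of exactly `period`.

    Greedy left-to-right construction: a segment absorbs the next point of
    this period as long as the running density (points per enumeration
    position from the segment start) stays >= `min_density`; segments with
    fewer than `min_run` points are discarded.  The returned intervals
    delimit candidate HOR arrays.
    """
    enums = sorted(p.enumeration for p in points if p.period == period)
    segments: list[tuple[int, int]] = []
    if not enums:
        return segments
    seg_start = prev = enums[0]
    count = 1
    for e in enums[1:]:
        if (count + 1) / (e - seg_start + 1) >= min_density:
            prev = e
            count += 1
        else:
            if count >= min_run:
                segments.append((seg_start, prev))
            seg_start = prev = e
            count = 1
    if count >= min_run:
        segments.append((seg_start, prev))
    return segments


def frequency_table(hist: PeriodHistogram, min_freq: int = 90) -> pd.DataFrame:
    """Period/frequency table, reporting only periods with frequency > `min_freq`."""
    rows = [(p, f) for p, f in sorted(hist.freq.items()) if f > min_freq]
    return pd.DataFrame(rows, columns=["period", "frequency"])
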
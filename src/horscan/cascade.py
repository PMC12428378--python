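"""Aligned multi-row HOR schematics (cascading layout) and Willard/cascading typing.

The scheme places a HOR unit's monomers on a grid where every row holds
distinct types and every column holds a single type.  The layout is greedy:
a cursor tracks the last placement column; a monomer of an already-seen
type goes to its column when that column lies right of the cursor and
otherwise starts a new row there; a new type opens a fresh column
immediately right of the cursor.  Flattening the scheme row by row, left
to right, reproduces the unit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

__all__ = ["CascadeScheme", "layout_cascade", "classify_hor_type", "align_variant_schemes"]


@dataclass
class CascadeScheme:
    columns: list[int]  # type id per column, left to right
    placements: list[tuple[int, int, int, int]]  # (row, column, enumeration offset, type id)
    extra_types: list[int] = field(default_factory=list)  # types appended beyond a fixed column order

    @property
    def n_rows(self) -> int:
        return max(r for r, _, _, _ in self.placements) + 1 if self.placements else 0

    @property
    def row_counts(self) -> list[int]:
        counts = [0] * self.n_rows
        for r, _, _, _ in self.placements:
            counts[r] += 1
        return counts

    def rows(self) -> list[list[int]]:
        """Type ids per row, left to right."""
        out: list[list[int]] = [[] for _ in range(self.n_rows)]
        for r, _, off, t in sorted(self.placements, key=lambda p: (p[0], p[2])):
            out[r].append(t)
        return out

    def flatten(self) -> list[int]:
        """Reading the scheme row by row reproduces the unit's type sequence."""
        return [t for _, _, _, t in sorted(self.placements, key=lambda p: p[2])]


def layout_cascade(unit_type_seq: Sequence[int], column_order: Sequence[int] | None = None) -> CascadeScheme:
    """Greedy cascading layout of one HOR unit.

    With `column_order` given (the canonical unit's columns), those columns
    are fixed; types absent from it are appended as flagged extra columns.
    """
    if not unit_type_seq:
        raise ValueError("layout_cascade requires a non-empty unit")
    fixed = column_order is not None
    columns: list[int] = list(column_order) if fixed else []
    col_of: dict[int, int] = {t: i for i, t in enumerate(columns)}
    extra: list[int] = []
    raw: list[tuple[int, int, int]] = []  # (row, offset, type); columns resolved at the end
    cursor = -1
    row = 0
    for off, t in enumerate(unit_type_seq):
        if t in col_of:
            c = col_of[t]
            if off > 0 and c <= cursor:
                row += 1
        else:
            if fixed:
                c = len(columns)
                columns.append(t)
                extra.append(t)
            else:
                c = cursor + 1
                columns.insert(c, t)
                for k, v in col_of.items():
                    if v >= c:
                        col_of[k] = v + 1
            col_of[t] = c
        c = col_of[t]
        raw.append((row, off, t))
        cursor = c
    placements = [(r, col_of[t], off, t) for r, off, t in raw]
    return CascadeScheme(columns=columns, placements=placements, extra_types=extra)


def classify_hor_type(scheme: CascadeScheme) -> str:
    """'Willard' when the unit has no repeated type (single row), else 'Cascading'."""
    return "Willard" if scheme.n_rows == 1 else "Cascading"


def _align_rows(variant_rows: list[list[int]], canon_rows: list[list[int]]) -> list[Optional[int]]:
    """Match variant rows to canonical rows by maximal type overlap.

    Global alignment over row sequences scoring scaled |set overlap| with a
    small gap penalty so equal rows pair up; returns per variant row the
    canonical row index, or None for inserted rows.
    """
    m, n = len(variant_rows), len(canon_rows)
    GAP = -1  # integer scoring keeps tie comparisons exact
    score = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        score[i][0] = i * GAP
    for j in range(1, n + 1):
        score[0][j] = j * GAP
    overlap = [[1024 * len(set(vr) & set(cr)) for cr in canon_rows] for vr in variant_rows]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            score[i][j] = max(
                score[i - 1][j - 1] + overlap[i - 1][j - 1],
                score[i - 1][j] + GAP,
                score[i][j - 1] + GAP,
            )
    out: list[Optional[int]] = [None] * m
    i, j = m, n
    # at ties, prefer treating the later of two equal rows as the inserted
    # one, so a duplicated row lands in the slot after the row it repeats
    while i > 0 and j > 0:
        if score[i][j] == score[i - 1][j] + GAP:
            i -= 1
        elif score[i][j] == score[i - 1][j - 1] + overlap[i - 1][j - 1]:
            out[i - 1] = j - 1
            i, j = i - 1, j - 1
        else:
            j -= 1
    return out


def align_variant_schemes(
    canonical: CascadeScheme,
    variants: Sequence[CascadeScheme],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Row-aligned per-copy monomer-count table (canonical first).

    Columns hold per-row monomer counts in aligned row slots ('-' for rows a
    copy lacks); inserted variant rows (e.g. a duplicated canonical row) get
    their own slots right after the canonical row they repeat.  A final
    column gives each copy's total row count.
    """
    canon_rows = canonical.rows()
    n_canon = len(canon_rows)
    aligned = [_align_rows(v.rows(), canon_rows) for v in variants]
    # inserted rows are attributed to the slot after the last matched canonical row
    inserts_after = [0] * (n_canon + 1)
    per_variant_layout = []
    for v, amap in zip(variants, aligned):
        layout: list[tuple[int, int, int]] = []  # (canon_row or -1, insert_ordinal, variant_row)
        last = -1
        pending = 0
        for vi, cj in enumerate(amap):
            if cj is None:
                pending += 1
                layout.append((last, pending, vi))
            else:
                last = cj
                pending = 0
                layout.append((cj, 0, vi))
        per_variant_layout.append(layout)
        counts_after: dict[int, int] = {}
        for cj, ordinal, _ in layout:
            if ordinal:
                counts_after[cj] = max(counts_after.get(cj, 0), ordinal)
        for cj, k in counts_after.items():
            inserts_after[cj + 1] = max(inserts_after[cj + 1], k)
    # slot order: [inserts after row -1] then for each canonical row: the row, then its insert slots
    slots: list[tuple[int, int]] = [(-1, k) for k in range(1, inserts_after[0] + 1)]
    for cj in range(n_canon):
        slots.append((cj, 0))
        slots.extend((cj, k) for k in range(1, inserts_after[cj + 1] + 1))
    slot_index = {s: i for i, s in enumerate(slots)}

    def row_counts_for(scheme: CascadeScheme, layout) -> list:
        cells: list = ["-"] * len(slots)
        rc = scheme.row_counts
        for cj, ordinal, vi in layout:
            cells[slot_index[(cj, ordinal)]] = rc[vi]
        return cells + [scheme.n_rows]

    canon_layout = [(j, 0, j) for j in range(n_canon)]
    data = [row_counts_for(canonical, canon_layout)]
    index = [f"C{sum(canonical.row_counts)}"]
    for k, (v, layout) in enumerate(zip(variants, per_variant_layout)):
        data.append(row_counts_for(v, layout))
        index.append(labels[k + 1] if labels else f"V{sum(v.row_counts)}")
    cols = [f"row_{i + 1}" for i in range(len(slots))] + ["n_rows"]
    return pd.DataFrame(data, index=index, columns=cols)
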
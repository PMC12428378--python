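"""Monomer type classification under the <5% divergence rule.

Monomers mutually diverged by less than 5% belong to one type.  Assignment
is greedy with static centroids: scanning in enumeration order, a monomer
joins the first existing type whose centroid (the founding monomer's
sequence) lies strictly below the threshold, otherwise it founds a new type.
Static centroids avoid the chaining of single-linkage clustering, which
could merge types more than 5% apart, and make the assignment order-stable.

A second pass (:func:`reconcile_types_with_columns`) re-checks monomers
against the column structure of a provisional HOR segmentation: a monomer
whose aligned column is dominated by another type, and whose sequence lies
within the threshold of that type's centroid, is reassigned.  This ties the
type assignment to the positional architecture of the array.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

from .align import global_divergence

if TYPE_CHECKING:  # pragma: no cover
    from .hor import HORCopy

__all__ = ["TypeAssignment", "pairwise_divergence", "cluster_types", "reconcile_types_with_columns"]

DEFAULT_TYPE_THRESHOLD = 0.05


def pairwise_divergence(a: str, b: str) -> float:
    """Edit-distance divergence between two DNA strings (fraction in [0, 1])."""
    return global_divergence(a, b)


@dataclass
class TypeAssignment:
    """Mapping from monomer enumeration (1-based) to dense type ids."""

    types: dict[int, int]
    centroids: dict[int, str]

    @property
    def n_types(self) -> int:
        return len(self.centroids)

    def type_seq(self, enums: Sequence[int] | None = None) -> list[int]:
        """Type ids in enumeration order (all enumerations by default)."""
        if enums is None:
            enums = sorted(self.types)
        return [self.types[e] for e in enums]


def cluster_types(
    oriented_seqs: Sequence[str],
    type_threshold: float = DEFAULT_TYPE_THRESHOLD,
    start_enum: int = 1,
) -> TypeAssignment:
    """Greedy static-centroid clustering of strand-corrected monomer sequences.

    `oriented_seqs[i]` is the monomer with enumeration `start_enum + i`.
    Type ids are dense 1..n_types, numbered by first occurrence.
    """
    types: dict[int, int] = {}
    centroids: dict[int, str] = {}
    cache: dict[str, int] = {}
    for i, seq in enumerate(oriented_seqs):
        if not seq:
            raise ValueError(f"empty monomer sequence at enumeration {start_enum + i}")
        tid = cache.get(seq)
        if tid is None:
            for cand, cent in centroids.items():
                if global_divergence(seq, cent) < type_threshold:
                    tid = cand
                    break
            if tid is None:
                tid = len(centroids) + 1
                centroids[tid] = seq
            cache[seq] = tid
        types[start_enum + i] = tid
    return TypeAssignment(types=types, centroids=centroids)


def _renumber(assignment: TypeAssignment) -> TypeAssignment:
    """Renumber type ids to dense 1..K by first occurrence in enumeration order."""
    remap: dict[int, int] = {}
    for enum in sorted(assignment.types):
        old = assignment.types[enum]
        if old not in remap:
            remap[old] = len(remap) + 1
    types = {e: remap[t] for e, t in assignment.types.items()}
    centroids = {remap[t]: c for t, c in assignment.centroids.items() if t in remap}
    return TypeAssignment(types=types, centroids=centroids)


def reconcile_types_with_columns(
    assignment: TypeAssignment,
    copies: Sequence["HORCopy"],
    type_threshold: float = DEFAULT_TYPE_THRESHOLD,
) -> TypeAssignment:
    """Re-check monomer types against aligned columns across HOR copies.

    Each copy must carry a `col_map` (from monomer-by-monomer alignment to
    the canonical unit, None for inserted monomers).  A monomer whose
    column-majority type differs from its own, and whose sequence is within
    `type_threshold` of the majority centroid, is reassigned.  Idempotent on
    column-consistent input; the result is renumbered dense.
    """
    columns: dict[int, list[tuple[int, int, str]]] = {}
    for copy in copies:
        col_map = copy.col_map if copy.col_map is not None else range(len(copy.type_seq))
        for offset, col in enumerate(col_map):
            if col is None:
                continue
            enum = copy.start_enum + offset
            columns.setdefault(col, []).append(
                (enum, assignment.types[enum], copy.monomer_seqs[offset])
            )
    new_types = dict(assignment.types)
    for members in columns.values():
        counts = Counter(t for _, t, _ in members)
        majority, _ = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        cent = assignment.centroids[majority]
        for enum, tid, seq in members:
            if tid != majority and global_divergence(seq, cent) < type_threshold:
                new_types[enum] = majority
    return _renumber(TypeAssignment(types=new_types, centroids=dict(assignment.centroids)))
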
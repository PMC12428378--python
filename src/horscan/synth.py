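"""Synthetic alpha-satellite array generation with full ground truth.

The generator emulates the structures the pipeline is built to detect:
tandem monomer arrays drawn from a planted type library (pairwise inter-type
divergence controlled, default 15%), HOR units whose type sequence may
repeat types (cascading) or not (Willard-type), canonical copies mutated
i.i.d. per base (default substitution rate 0.25%, the scale of canonical
HOR homogeneity in complete great-ape Y centromeres), interspersed
structural variants built by duplicating or deleting unit slices, random
flanking DNA and optional N-gaps.  Mutations are substitutions only unless
an indel rate is explicitly requested, which keeps divergence arithmetic
exact for calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .monomer_types import pairwise_divergence
from .monomers import ConsensusMonomer, default_consensus
from .seqio import GenomeSequence

__all__ = [
    "SyntheticHORSpec",
    "SyntheticArray",
    "make_type_library",
    "apply_edits",
    "generate_array",
    "random_dna",
    "unit_from_row_windows",
]

_BASES = np.array(list("ACGT"))
DEFAULT_TYPE_THRESHOLD = 0.05


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def unit_from_row_windows(windows: Sequence[tuple[int, int]]) -> list[int]:
    """Build a cascading unit as consecutive column windows (1-based, inclusive).

    Each window is one row of the aligned scheme; a row must start at or
    left of the previous row's end for the greedy layout to reproduce the
    row structure.  E.g. ``[(1, 13), (12, 27), (26, 32), (30, 33), (27, 44)]``
    yields a 58-monomer unit over 44 types with rows 13/16/7/4/18.
    """
    unit: list[int] = []
    prev_end = None
    for start, end in windows:
        if start > end or start < 1:
            raise ValueError(f"bad column window {(start, end)}")
        if prev_end is not None and start > prev_end:
            raise ValueError("row window must start at or left of the previous row's end")
        unit.extend(range(start, end + 1))
        prev_end = end
    return unit


def apply_edits(unit: Sequence[int], edits: Sequence[tuple]) -> list[int]:
    """Apply structural edits to a unit's type sequence.

    Edits are ``("dup", start, length)`` (duplicate the slice, inserting the
    copy right after it), ``("del", start, length)``, or
    ``("ins", start, type_id)`` (insert one monomer of the given type before
    `start`); `start` is a 0-based monomer offset.  Applied left to right in
    the given order.
    """
    out = list(unit)
    for edit in edits:
        op, start, arg = edit
        if op == "dup":
            out = out[: start + arg] + out[start : start + arg] + out[start + arg :]
        elif op == "del":
            out = out[:start] + out[start + arg :]
        elif op == "ins":
            out = out[:start] + [arg] + out[start:]
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return out


@dataclass
class SyntheticHORSpec:
    """Ground-truth description of one synthetic HOR array."""

    unit_type_seq: list[int]
    n_copies: int
    cv_pattern: Optional[str] = None  # default: all canonical
    variant_edits: Optional[dict[int, list[tuple]]] = None  # copy index -> edits
    per_base_mut_rate: float = 0.0025
    inter_type_div: float = 0.15
    flank_bp: int = 2000
    n_gap: Optional[tuple[int, int]] = None  # (position within array sequence, length)
    rng_seed: int = 0
    scan_min_identity: float = 0.90  # detectability constraint for the type library
    type_threshold: float = DEFAULT_TYPE_THRESHOLD

    def __post_init__(self) -> None:
        if self.cv_pattern is not None and len(self.cv_pattern) != self.n_copies:
            raise ValueError("cv_pattern length must equal n_copies")
        if not self.inter_type_div > 2 * self.type_threshold:
            raise ValueError("inter_type_div must exceed twice the type threshold for unambiguous types")

    @property
    def k_types(self) -> int:
        return max(self.unit_type_seq)


@dataclass
class SyntheticArray:
    sequence: GenomeSequence
    monomers: pd.DataFrame  # start, end, type, copy_index, strand
    copies: pd.DataFrame  # start, end, label, m
    library: list[str]
    spec: SyntheticHORSpec


def _mutate(seq: str, rate: float, rng: np.random.Generator, indel_rate: float = 0.0) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    out = "".join(arr)
    if indel_rate > 0:
        chars = list(out)
        i = 0
        res = []
        while i < len(chars):
            r = rng.random()
            if r < indel_rate / 2:
                i += 1  # deletion
                continue
            if r < indel_rate:
                res.append(chars[i])
                res.append("ACGT"[rng.integers(0, 4)])  # insertion after
                i += 1
                continue
            res.append(chars[i])
            i += 1
        out = "".join(res)
    return out


def make_type_library(
    k_types: int,
    consensus: str | ConsensusMonomer,
    inter_type_div: float = 0.15,
    rng_seed: int = 0,
    max_div_to_consensus: Optional[float] = None,
) -> list[str]:
    """Plant `k_types` monomer types, pairwise >= `inter_type_div` apart.

    When the types must stay detectable by the consensus scan, pass
    `max_div_to_consensus` (about 1 - min_identity minus a margin).  Small
    libraries use disjoint mutation position sets, which meet the pairwise
    bound exactly; larger ones use random mutation sets with rejection
    resampling.  Raises when the constraints are unsatisfiable.
    """
    cons = consensus.sequence if isinstance(consensus, ConsensusMonomer) else consensus
    L = len(cons)
    rng = np.random.default_rng(rng_seed)
    if k_types < 1:
        raise ValueError("k_types must be >= 1")
    if k_types == 1:
        return [cons]
    need = math.ceil(inter_type_div * L)  # min pairwise differing columns
    d = math.ceil(inter_type_div * L / 2)
    dmax = math.floor(max_div_to_consensus * L) if max_div_to_consensus is not None else L
    if 2 * dmax < need:
        raise ValueError(
            f"cannot plant types {inter_type_div:.0%} apart while keeping each within "
            f"{max_div_to_consensus:.0%} of the consensus"
        )
    d = min(max(d, 1), dmax)

    def mutate_at(positions: np.ndarray) -> str:
        arr = list(cons)
        for p in positions:
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(0, 3)]
        return "".join(arr)

    # Disjoint mutation sets give exactly 2d differing columns per pair, but
    # the alignment-length-normalized divergence can dip just below 2d/L
    # when indels shorten the optimal path; verify and bump d if needed.
    while k_types * d <= L and 2 * d >= need and d <= dmax:
        positions = rng.permutation(L)
        lib = [mutate_at(np.sort(positions[i * d : (i + 1) * d])) for i in range(k_types)]
        ok = all(
            pairwise_divergence(lib[i], lib[j]) >= inter_type_div
            for i in range(k_types)
            for j in range(i + 1, k_types)
        )
        if ok:
            return lib
        d += 1

    d2 = min(math.ceil(d * 1.35) + 1, dmax)
    if 2 * d2 < need:
        raise ValueError(f"constraints unsatisfiable for k={k_types} at inter_type_div={inter_type_div}")
    lib = [mutate_at(np.sort(rng.choice(L, size=d2, replace=False))) for _ in range(k_types)]
    for _round in range(500):
        bad: set[int] = set()
        for i in range(k_types):
            for j in range(i + 1, k_types):
                if i in bad and j in bad:
                    continue
                if pairwise_divergence(lib[i], lib[j]) < inter_type_div:
                    bad.add(j)
        if not bad:
            return lib
        for j in bad:
            lib[j] = mutate_at(np.sort(rng.choice(L, size=d2, replace=False)))
    raise ValueError(
        f"could not satisfy inter-type divergence {inter_type_div} for k={k_types} "
        f"within the consensus-distance budget"
    )


def _default_variant_edit(unit_len: int, rng: np.random.Generator) -> list[tuple]:
    length = max(1, unit_len // 4)
    start = 1 + int(rng.integers(0, max(1, unit_len - length - 1)))
    return [("dup", start, length)]


def generate_array(
    spec: SyntheticHORSpec,
    consensus: ConsensusMonomer | None = None,
    library: Sequence[str] | None = None,
) -> SyntheticArray:
    """Emit the synthetic sequence plus monomer- and copy-level truth tables.

    Passing a prebuilt `library` lets several arrays (e.g. two HOR families
    on one chromosome) share one type universe.
    """
    cons = consensus or default_consensus()
    rng = np.random.default_rng(spec.rng_seed)
    max_div = max((1.0 - spec.scan_min_identity) - 0.01, spec.inter_type_div / 2)
    k_needed = max(
        spec.k_types,
        max(
            (e[2] for edits in (spec.variant_edits or {}).values() for e in edits if e[0] == "ins"),
            default=0,
        ),
    )
    lib = (
        list(library)
        if library is not None
        else make_type_library(
            k_needed, cons, spec.inter_type_div, rng_seed=spec.rng_seed, max_div_to_consensus=max_div
        )
    )
    cv = spec.cv_pattern or "C" * spec.n_copies
    mono_rows = []
    copy_rows = []
    parts: list[str] = []
    pos = spec.flank_bp
    left_flank = random_dna(spec.flank_bp, rng)
    for ci, label in enumerate(cv):
        if label == "C":
            unit = list(spec.unit_type_seq)
        else:
            edits = (spec.variant_edits or {}).get(ci)
            if edits is None:
                edits = _default_variant_edit(len(spec.unit_type_seq), rng)
            unit = apply_edits(spec.unit_type_seq, edits)
        copy_start = pos
        for offset, t in enumerate(unit):
            mono = _mutate(lib[t - 1], spec.per_base_mut_rate, rng)
            mono_rows.append(
                {"start": pos, "end": pos + len(mono), "type": t, "copy_index": ci, "strand": "+"}
            )
            parts.append(mono)
            pos += len(mono)
        copy_rows.append(
            {
                "start": copy_start,
                "end": pos,
                "label": "C" if label == "C" else f"V{len(unit)}",
                "m": len(unit),
            }
        )
    right_flank = random_dna(spec.flank_bp, rng)
    bases = left_flank + "".join(parts) + right_flank
    if spec.n_gap is not None:
        g0, glen = spec.n_gap
        bases = bases[:g0] + "N" * glen + bases[g0 + glen :]
    seq = GenomeSequence(name=f"synth_hor_{spec.rng_seed}", bases=bases)
    return SyntheticArray(
        sequence=seq,
        monomers=pd.DataFrame(mono_rows),
        copies=pd.DataFrame(copy_rows),
        library=lib,
        spec=spec,
    )
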
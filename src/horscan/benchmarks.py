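"""Synthetic analogs of the great-ape Y-centromere HOR architectures.

These builders plant, with full ground truth, the published structural
organization of the dominant alpha-satellite HOR arrays in complete Y
chromosome assemblies:

* orangutan — a cascading 58mer superHOR (44 distinct types, 14 repeated,
  five-row scheme 13/16/7/4/18, canonical/variant arrangement of 310 copies
  with 258 canonical, ~0.25% canonical divergence) plus a weakly cascading
  45mer (37 distinct types, rows 35/9/1, ~0.81% divergence);
* human — a Willard-type 34mer (54 copies, 49 canonical) with 46/44mer
  variants at the array start and 36mer variants at the end;
* chimpanzee — a Willard-type 28mer (259 copies, 237 canonical);
* gorilla — a cascading 18mer of monomer doublets (t1 tn), 779 copies with
  405 canonical, where the period-2 subfragment outnumbers the full unit.

The monomer type library is synthetic (planted mutations of the shipped
consensus); what is reproduced is the higher-order structure, not the
nucleotide sequences of any real centromere.  Copy counts can be scaled
down for quick runs; structural proportions are preserved.
"""

from __future__ import annotations

import numpy as np

from .monomers import ConsensusMonomer, default_consensus
from .seqio import GenomeSequence
from .synth import SyntheticHORSpec, generate_array, make_type_library, random_dna, unit_from_row_windows

__all__ = [
    "ORANGUTAN_Y_58MER_CV",
    "orangutan_58mer_unit",
    "orangutan_45mer_unit",
    "gorilla_18mer_unit",
    "orangutan_y_analog",
    "human_y_analog",
    "chimpanzee_y_analog",
    "gorilla_y_analog",
]

# Published canonical (C) / variant (V) arrangement of the orangutan Y 58mer
# array: 310 copies, 258 canonical, 52 variants.
ORANGUTAN_Y_58MER_CV = (
    "VCVVVCCCCCVVVVCVVVVVCCCCCCCCCCCVCCVCCCCCCCVVVVCCCVCCCCCCCCCCCCCCCCCCCCCCC"
    "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCVC"
    "VCCCCCCCCCCCCCCCCVCCVVCCCVCCCVVVCVCCVVVCVCCCCCCVCCCCCCCCCCCCCCCCCVVCVCVVC"
    "CCCCCVCCCCVCCCCVCCCCCCCCCCCCCCCCCCCCCCCCCCVVVVCCCVCCCCCCCVCCCCCCVCCCCCVVC"
    "CCCCCCCCCCCCCCCCCC"
)

# Library geometry: types ~7% from the consensus and >=11% apart keep every
# monomer within comfortable scan reach (identity >= 0.93 before copy
# mutations, scanned at 0.89) while staying unambiguous under the 5% typing
# rule even at the 0.81% mutation scale of the more divergent arrays.
_INTER_TYPE_DIV = 0.11
_MAX_DIV_TO_CONSENSUS = 0.075
_SCAN_MIN_IDENTITY = 0.89


def _build_library(k: int, seed: int, cons: ConsensusMonomer | None = None) -> list[str]:
    cons = cons or default_consensus()
    return make_type_library(
        k, cons, _INTER_TYPE_DIV, rng_seed=seed, max_div_to_consensus=_MAX_DIV_TO_CONSENSUS
    )


def orangutan_58mer_unit(type_offset: int = 0) -> list[int]:
    """58-monomer cascading unit over 44 types; greedy layout rows 13/16/7/4/18."""
    unit = unit_from_row_windows([(1, 13), (12, 27), (26, 32), (30, 33), (27, 44)])
    return [t + type_offset for t in unit]


def orangutan_45mer_unit(type_offset: int = 0) -> list[int]:
    """45-monomer weakly cascading unit over 37 types; rows 35/9/1."""
    unit = unit_from_row_windows([(1, 35), (29, 37), (37, 37)])
    return [t + type_offset for t in unit]


def gorilla_18mer_unit() -> list[int]:
    """18-monomer doublet unit (t1 t2 t1 t3 ... t1 t9): 9 doublets sharing t1."""
    unit: list[int] = []
    for partner in range(2, 11):
        unit.extend([1, partner])
    return unit


# Table-style structural variants of the 58mer, as monomer-offset edits of
# the canonical unit (rows: offsets 0-12 / 13-28 / 29-35 / 36-39 / 40-57).
# The V74 duplicates the second row; V90 duplicates it twice; V59 inserts an
# extra (novel-type) monomer in row 1; V57/V55 delete monomers from rows
# 2/5; V42 deletes row 2 entirely.
def _58mer_variant_edits(extra_type: int) -> list[list[tuple]]:
    return [
        [("dup", 13, 16)],  # V74
        [("dup", 13, 16)],  # V74
        [("dup", 13, 16), ("dup", 13, 16)],  # V90
        [("ins", 6, extra_type)],  # V59
        [("dup", 13, 16)],  # V74
        [("del", 20, 1)],  # V57
        [("del", 55, 3)],  # V55
        [("dup", 13, 16)],  # V74
        [("del", 13, 16)],  # V42
    ]


def _assign_variant_edits(cv: str, cycle: list[list[tuple]]) -> dict[int, list[tuple]]:
    out: dict[int, list[tuple]] = {}
    k = 0
    for i, c in enumerate(cv):
        if c == "V":
            out[i] = cycle[k % len(cycle)]
            k += 1
    return out


def _peripheral_cv(n_copies: int, n_canonical: int) -> str:
    """Canonical core with variants split between the two array ends."""
    n_var = n_copies - n_canonical
    left = n_var // 2
    return "V" * left + "C" * n_canonical + "V" * (n_var - left)


def _compose(parts: list[str], name: str) -> GenomeSequence:
    return GenomeSequence(name=name, bases="".join(parts))


def orangutan_y_analog(
    seed: int = 0,
    n_copies_58: int = 310,
    n_copies_45: int = 67,
    flank_bp: int = 2000,
    spacer_bp: int = 2000,
):
    """Orangutan-Y-like chromosome: 58mer superHOR array plus 45mer array.

    Returns (sequence, info); `info` carries the analysis parameters the
    arrays were built to be detected with and the planted ground truth.
    """
    cons = default_consensus()
    # one shared type universe: 58mer uses types 1-44 (+45 for the V59
    # insertion), 45mer uses 46-82
    lib = _build_library(82, seed, cons)
    full_cv = ORANGUTAN_Y_58MER_CV
    if n_copies_58 == len(full_cv):
        cv58 = full_cv
    elif n_copies_58 < len(full_cv):
        # proportional subsample preserving the canonical/variant mix
        idx = [round(i * (len(full_cv) - 1) / (n_copies_58 - 1)) for i in range(n_copies_58)]
        cv58 = "".join(full_cv[i] for i in idx)
    else:
        cv58 = (full_cv * (n_copies_58 // len(full_cv) + 1))[:n_copies_58]
    spec58 = SyntheticHORSpec(
        unit_type_seq=orangutan_58mer_unit(),
        n_copies=n_copies_58,
        cv_pattern=cv58,
        variant_edits=_assign_variant_edits(cv58, _58mer_variant_edits(extra_type=45)),
        per_base_mut_rate=0.0025,
        inter_type_div=_INTER_TYPE_DIV,
        flank_bp=0,
        rng_seed=seed,
        scan_min_identity=_SCAN_MIN_IDENTITY,
    )
    cv45 = _peripheral_cv(n_copies_45, n_copies_45 - max(2, n_copies_45 // 11))
    spec45 = SyntheticHORSpec(
        unit_type_seq=orangutan_45mer_unit(type_offset=45),
        n_copies=n_copies_45,
        cv_pattern=cv45,
        variant_edits=_assign_variant_edits(cv45, [[("dup", 35, 9)], [("del", 40, 5)]]),
        per_base_mut_rate=0.0081,
        inter_type_div=_INTER_TYPE_DIV,
        flank_bp=0,
        rng_seed=seed + 1,
        scan_min_identity=_SCAN_MIN_IDENTITY,
    )
    arr58 = generate_array(spec58, cons, library=lib)
    arr45 = generate_array(spec45, cons, library=lib)
    rng = np.random.default_rng(seed + 2)
    seq = _compose(
        [
            random_dna(flank_bp, rng),
            arr58.sequence.bases,
            random_dna(spacer_bp, rng),
            arr45.sequence.bases,
            random_dna(flank_bp, rng),
        ],
        name="orangutan_y_analog",
    )
    info = {
        "params": dict(min_identity=_SCAN_MIN_IDENTITY, min_run=20, min_density=0.5),
        "planted": {
            "period_major": 58,
            "period_minor": 45,
            "n_copies_major": n_copies_58,
            "n_canonical_major": cv58.count("C"),
            "n_copies_minor": n_copies_45,
            "n_canonical_minor": cv45.count("C"),
            "distinct_types_major": 44,
            "repeated_types_major": 14,
            "rows_major": [13, 16, 7, 4, 18],
            "distinct_types_minor": 37,
            "rows_minor": [35, 9, 1],
            "mut_rate_major": 0.0025,
            "mut_rate_minor": 0.0081,
            "cv_major": cv58,
        },
    }
    return seq, info


def _willard_analog(
    name: str,
    period: int,
    n_copies: int,
    n_canonical: int,
    variant_cycle: list[list[tuple]],
    seed: int,
    flank_bp: int = 2000,
):
    cv = _peripheral_cv(n_copies, n_canonical)
    spec = SyntheticHORSpec(
        unit_type_seq=list(range(1, period + 1)),
        n_copies=n_copies,
        cv_pattern=cv,
        variant_edits=_assign_variant_edits(cv, variant_cycle),
        per_base_mut_rate=0.0025,
        inter_type_div=_INTER_TYPE_DIV,
        flank_bp=flank_bp,
        rng_seed=seed,
        scan_min_identity=_SCAN_MIN_IDENTITY,
    )
    arr = generate_array(spec, library=_build_library(period, seed))
    seq = GenomeSequence(name=name, bases=arr.sequence.bases)
    info = {
        "params": dict(min_identity=_SCAN_MIN_IDENTITY, min_run=20, min_density=0.5),
        "planted": {
            "period": period,
            "n_copies": n_copies,
            "n_canonical": n_canonical,
            "cv": cv,
        },
    }
    return seq, info


def human_y_analog(seed: int = 0, n_copies: int = 54, n_canonical: int = 49):
    """Human-Y-like Willard 34mer array; 46/44mer variants first, 36mers last."""
    cycle = [
        [("dup", 10, 12)],  # V46 at the array start
        [("dup", 10, 10)],  # V44
        [("dup", 20, 2)],  # V36 at the array end
        [("dup", 25, 2)],  # V36
        [("dup", 15, 2)],  # V36
    ]
    return _willard_analog("human_y_analog", 34, n_copies, n_canonical, cycle, seed)


def chimpanzee_y_analog(seed: int = 0, n_copies: int = 259, n_canonical: int = 237):
    """Chimpanzee-Y-like Willard 28mer array."""
    cycle = [[("dup", 8, 3)], [("del", 12, 2)], [("dup", 5, 7)], [("del", 16, 1)]]
    return _willard_analog("chimpanzee_y_analog", 28, n_copies, n_canonical, cycle, seed)


def gorilla_y_analog(seed: int = 0, n_copies: int = 779, n_canonical: int = 405, flank_bp: int = 2000):
    """Gorilla-Y-like cascading 18mer doublet array.

    Doublet structure means at most 8 of 18 monomers recur at the full
    period, so the MD line segment at 18 needs `min_density` 0.4; the
    period-2 subfragment outnumbers the full unit, as observed in complete
    gorilla Y assemblies.
    """
    cv = _peripheral_cv(n_copies, n_canonical)
    spec = SyntheticHORSpec(
        unit_type_seq=gorilla_18mer_unit(),
        n_copies=n_copies,
        cv_pattern=cv,
        variant_edits=_assign_variant_edits(cv, [[("dup", 10, 2)], [("del", 8, 2)]]),
        per_base_mut_rate=0.0025,
        inter_type_div=_INTER_TYPE_DIV,
        flank_bp=flank_bp,
        rng_seed=seed,
        scan_min_identity=_SCAN_MIN_IDENTITY,
    )
    arr = generate_array(spec, library=_build_library(10, seed))
    seq = GenomeSequence(name="gorilla_y_analog", bases=arr.sequence.bases)
    info = {
        "params": dict(min_identity=_SCAN_MIN_IDENTITY, min_run=20, min_density=0.4),
        "planted": {"period": 18, "n_copies": n_copies, "n_canonical": n_canonical, "cv": cv},
    }
    return seq, info
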
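"""Ground-truth array generation: library constraints, edits, truth tables."""

import numpy as np
import pytest

import horscan as hs
from horscan.monomer_types import pairwise_divergence
from horscan.monomers import scan_monomers
from horscan.synth import (
    SyntheticHORSpec,
    apply_edits,
    generate_array,
    make_type_library,
    unit_from_row_windows,
)


class TestMakeTypeLibrary:
    def test_single_type_is_the_consensus(self, consensus):
        assert make_type_library(1, consensus) == [consensus.sequence]

    def test_three_types_pairwise_divergence_in_band(self, consensus):
        lib = make_type_library(3, consensus, inter_type_div=0.15, rng_seed=1)
        for i in range(3):
            for j in range(i + 1, 3):
                d = pairwise_divergence(lib[i], lib[j])
                assert 0.15 <= d <= 0.25

    def test_same_seed_reproduces_library(self, consensus):
        a = make_type_library(8, consensus, rng_seed=42)
        b = make_type_library(8, consensus, rng_seed=42)
        assert a == b

    def test_large_library_meets_constraints(self, consensus):
        lib = make_type_library(
            44, consensus, inter_type_div=0.11, rng_seed=2, max_div_to_consensus=0.075
        )
        assert len(lib) == 44
        for s in lib:
            assert pairwise_divergence(s, consensus.sequence) <= 0.075
        rng = np.random.default_rng(0)
        for _ in range(60):  # spot-check random pairs
            i, j = rng.choice(44, size=2, replace=False)
            assert pairwise_divergence(lib[i], lib[j]) >= 0.11

    def test_unsatisfiable_constraints_raise(self, consensus):
        with pytest.raises(ValueError):
            make_type_library(5, consensus, inter_type_div=0.3, max_div_to_consensus=0.05)


class TestApplyEdits:
    def test_duplication(self):
        assert apply_edits([1, 2, 3, 4], [("dup", 1, 2)]) == [1, 2, 3, 2, 3, 4]

    def test_deletion(self):
        assert apply_edits([1, 2, 3, 4], [("del", 1, 2)]) == [1, 4]

    def test_insertion(self):
        assert apply_edits([1, 2, 3], [("ins", 1, 9)]) == [1, 9, 2, 3]

    def test_unknown_op(self):
        with pytest.raises(ValueError):
            apply_edits([1], [("swap", 0, 1)])


def test_unit_from_row_windows_58mer_shape():
    unit = unit_from_row_windows([(1, 13), (12, 27), (26, 32), (30, 33), (27, 44)])
    assert len(unit) == 58 and len(set(unit)) == 44


def test_unit_from_row_windows_rejects_detached_row():
    with pytest.raises(ValueError):
        unit_from_row_windows([(1, 5), (7, 9)])


class TestGenerateArray:
    def test_truth_tables_consistent(self):
        spec = SyntheticHORSpec(unit_type_seq=[1, 2, 3], n_copies=4, rng_seed=0)
        arr = generate_array(spec)
        assert len(arr.monomers) == 12
        assert len(arr.copies) == 4
        assert arr.monomers.iloc[0].start == spec.flank_bp
        assert (arr.copies["label"] == "C").all()
        # monomer intervals tile the copies exactly
        assert arr.monomers.iloc[-1].end == arr.copies.iloc[-1].end

    def test_cv_pattern_length_validated(self):
        with pytest.raises(ValueError):
            SyntheticHORSpec(unit_type_seq=[1, 2], n_copies=3, cv_pattern="CC")

    def test_inter_type_div_must_exceed_twice_threshold(self):
        with pytest.raises(ValueError):
            SyntheticHORSpec(unit_type_seq=[1, 2], n_copies=3, inter_type_div=0.08)

    def test_willard_fixture_end_to_end(self):
        # 5 copies of a 3-type unit, zero mutation: the pipeline reports
        # period 3 and 4 full copies (edges dropped), all canonical
        spec = SyntheticHORSpec(
            unit_type_seq=[1, 2, 3], n_copies=5, per_base_mut_rate=0.0, rng_seed=11
        )
        arr = generate_array(spec)
        res = hs.analyze([arr.sequence], min_identity=0.90, min_run=5)
        assert len(res.hits) == 15
        fam = res.families[0].family
        assert fam.period == 3
        assert len(fam.copies) == 4
        assert fam.cv_string == "CCCC"

    def test_cascading_fixture_recovers_planted_cv(self):
        cv = "C" * 10 + "V" + "C" * 9 + "V" + "C" * 9
        spec = SyntheticHORSpec(
            unit_type_seq=[1, 2, 3, 4, 2, 3, 4, 5],
            n_copies=30,
            cv_pattern=cv,
            variant_edits={10: [("dup", 4, 4)], 20: [("del", 1, 1)]},
            rng_seed=2,
        )
        arr = generate_array(spec)
        res = hs.analyze([arr.sequence], min_identity=0.90, min_run=10, min_density=0.2)
        fam = res.families[0].family
        assert fam.period == 8
        assert fam.cv_string == cv[:-1]
        assert res.families[0].hor_type == "Cascading"

    def test_n_gap_removes_monomers_of_affected_copy(self):
        spec = SyntheticHORSpec(
            unit_type_seq=[1, 2, 3], n_copies=8, per_base_mut_rate=0.0, rng_seed=3
        )
        arr = generate_array(spec)
        # place a 150 bp N-gap inside copy 3 (0-based copy index 2)
        gap_pos = int(arr.copies.iloc[2].start) + 100
        spec_gap = SyntheticHORSpec(
            unit_type_seq=[1, 2, 3],
            n_copies=8,
            per_base_mut_rate=0.0,
            rng_seed=3,
            n_gap=(gap_pos, 150),
        )
        arr_gap = generate_array(spec_gap)
        res = hs.analyze([arr_gap.sequence], min_identity=0.90, min_run=4)
        assert len(res.hits) < 24  # gap-overlapping monomers excluded
        fam = res.families[0].family
        assert fam.period == 3
        assert len(fam.copies) < 7  # copy count reduced relative to gapless run

    def test_truth_monomers_recovered_with_reciprocal_overlap(self, consensus):
        spec = SyntheticHORSpec(
            unit_type_seq=[1, 2, 3, 4], n_copies=10, rng_seed=7, inter_type_div=0.11
        )
        arr = generate_array(spec)
        hits = scan_monomers(arr.sequence, consensus, min_identity=0.89)
        starts = {h.start: h for h in hits}
        matched = 0
        for row in arr.monomers.itertuples():
            best = None
            for h in hits:
                inter = min(h.end, row.end) - max(h.start, row.start)
                if inter > 0.95 * (row.end - row.start) and inter > 0.95 * (h.end - h.start):
                    best = h
                    break
            matched += best is not None
        assert matched == len(arr.monomers)

    def test_determinism_of_generation(self):
        spec = SyntheticHORSpec(unit_type_seq=[1, 2, 3], n_copies=5, rng_seed=9)
        a = generate_array(spec)
        b = generate_array(spec)
        assert a.sequence.bases == b.sequence.bases
        assert a.monomers.equals(b.monomers)
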
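"""HOR copy segmentation, C/V classification, consensus and divergence."""

import numpy as np
import pytest

from horscan.hor import (
    HORCopy,
    classify_copies,
    define_canonical,
    divergence_stats,
    family_consensus,
    pick_anchor_and_segment,
)

from conftest import mutate


def _copies_from(type_seqs):
    out = []
    enum = 1
    for ts in type_seqs:
        out.append(HORCopy(start_enum=enum, type_seq=list(ts)))
        enum += len(ts)
    return out


class TestAnchorSegmentation:
    def test_exact_periodic_block_drops_edges(self):
        seq = [1, 2, 3, 4, 5] * 10
        copies = pick_anchor_and_segment(seq, (1, len(seq)), 5)
        assert len(copies) == 9
        assert all(c.m == 5 for c in copies)
        assert [c.start_enum for c in copies] == [1 + 5 * i for i in range(9)]

    def test_insertion_variant_between_anchors(self):
        unit = [1, 2, 3, 4, 5]
        seqs = unit * 4 + [1, 2, 3, 9, 9, 4, 5] + unit * 4
        copies = pick_anchor_and_segment(seqs, (1, len(seqs)), 5)
        lengths = [c.m for c in copies]
        assert lengths.count(7) == 1 and lengths.count(5) == len(lengths) - 1

    def test_aperiodic_input_gives_no_copies(self):
        seq = list(range(1, 40))
        assert pick_anchor_and_segment(seq, (1, 39), 5) == []

    def test_segment_shorter_than_two_periods(self):
        seq = [1, 2, 3] * 3
        assert pick_anchor_and_segment(seq, (1, 5), 3) == []


class TestDefineCanonical:
    def test_unanimous(self):
        copies = _copies_from([[1, 2, 3, 4, 5]] * 9)
        assert define_canonical(copies, 5) == [1, 2, 3, 4, 5]

    def test_majority_wins(self):
        x, y = [1, 2, 3], [1, 3, 2]
        copies = _copies_from([y] + [x] * 6 + [y] * 2)
        assert define_canonical(copies, 3) == x

    def test_tie_broken_by_earliest_occurrence(self):
        x, y = [1, 2, 3], [1, 3, 2]
        copies = _copies_from([y, x, y, x, y, x])
        assert define_canonical(copies, 3) == y

    def test_off_length_copies_ignored_for_definition(self):
        copies = _copies_from([[1, 2, 3, 4]] * 5 + [[1, 2, 3]] * 2)
        assert define_canonical(copies, 3) == [1, 2, 3]


class TestClassifyCopies:
    def test_exact_match_is_canonical(self):
        canon = [1, 2, 3, 4, 5]
        fam = classify_copies(_copies_from([canon] * 3), canon)
        assert fam.cv_string == "CCC"
        assert all(c.label == "C" for c in fam.copies)

    def test_second_row_duplication_named_by_monomer_count(self):
        # cascading analog: canonical [1,2,3,4,2,3,4,5]; repeating the
        # second row (2,3,4,5) extends the copy to 12 monomers -> V12
        canon = [1, 2, 3, 4, 2, 3, 4, 5]
        variant = [1, 2, 3, 4, 2, 3, 4, 5, 2, 3, 4, 5]
        fam = classify_copies(_copies_from([canon, variant, canon]), canon)
        assert [c.label for c in fam.copies] == ["C", "V12", "C"]
        assert fam.cv_string == "CVC"
        assert fam.n_canonical == 2 and fam.n_variant == 1

    def test_substitution_same_length_is_still_variant(self):
        canon = [1, 2, 3, 4, 5]
        sub = [1, 2, 9, 4, 5]
        fam = classify_copies(_copies_from([canon, sub]), canon)
        assert [c.label for c in fam.copies] == ["C", "V5"]

    def test_count_conservation(self):
        canon = [1, 2, 3]
        seqs = [[1, 2, 3], [1, 3], [1, 2, 2, 3], [1, 2, 3]]
        fam = classify_copies(_copies_from(seqs), canon)
        assert fam.n_canonical + fam.n_variant == len(fam.copies) == len(fam.cv_string)

    def test_idempotence_of_reclassification(self):
        canon = [1, 2, 3, 4]
        seqs = [[1, 2, 3, 4], [1, 2, 4], [1, 2, 3, 4]]
        fam1 = classify_copies(_copies_from(seqs), canon)
        fam2 = classify_copies(fam1.copies, define_canonical(fam1.copies, 4))
        assert [c.label for c in fam2.copies] == [c.label for c in fam1.copies]

    def test_variant_col_map_marks_insertions(self):
        canon = [1, 2, 3]
        fam = classify_copies(_copies_from([[1, 2, 9, 9, 3]]), canon)
        cm = fam.copies[0].col_map
        assert cm[0] == 0 and cm[-1] == 2
        assert cm.count(None) >= 1  # at least one inserted monomer


class TestFamilyConsensus:
    def _copies(self, monomer_lists):
        out = []
        enum = 1
        for monos in monomer_lists:
            out.append(
                HORCopy(
                    start_enum=enum,
                    type_seq=list(range(1, len(monos) + 1)),
                    monomer_seqs=list(monos),
                    label="C",
                )
            )
            enum += len(monos)
        return out

    def test_identical_copies(self, consensus):
        copies = self._copies([[consensus.sequence] * 3] * 4)
        assert family_consensus(copies) == consensus.sequence * 3

    def test_majority_restores_substitution(self, consensus):
        clean = consensus.sequence
        noisy = mutate(clean, [42])
        copies = self._copies([[clean], [clean], [noisy]])
        assert family_consensus(copies) == clean

    def test_two_way_tie_breaks_alphabetically(self):
        a = "AAAA"
        c = "ACAA"  # position 1: A vs C, 1-1 tie -> 'A'
        copies = self._copies([[a], [c]])
        assert family_consensus(copies) == "AAAA"

    def test_single_copy_has_zero_divergence(self, consensus):
        copies = self._copies([[consensus.sequence]])
        cons = family_consensus(copies)
        stats = divergence_stats(copies, cons)
        assert stats.mean_pct == 0.0 and stats.n_canonical == 1


class TestDivergenceStats:
    def test_identical_copies_zero(self, consensus):
        copies = [
            HORCopy(1, [1], [consensus.sequence], label="C"),
            HORCopy(2, [1], [consensus.sequence], label="C"),
        ]
        stats = divergence_stats(copies, consensus.sequence)
        assert stats.per_copy == [0.0, 0.0] and stats.mean_pct == 0.0

    def test_binomial_calibration_at_0p25_pct(self, consensus):
        # 50 copies of a 58-monomer unit mutated at 2.5e-3 per base: the
        # mean divergence from the voted consensus must recover the planted
        # rate within 2 standard errors (and well within +-0.05 pp)
        rng = np.random.default_rng(20)
        unit_len, rate, n_copies = 58, 0.0025, 50
        master = [consensus.sequence] * unit_len
        copies = []
        for i in range(n_copies):
            monos = []
            for m in master:
                sites = np.nonzero(rng.random(len(m)) < rate)[0]
                monos.append(mutate(m, sites))
            copies.append(
                HORCopy(1 + i * unit_len, list(range(1, unit_len + 1)), monos, label="C")
            )
        cons = family_consensus(copies)
        stats = divergence_stats(copies, cons)
        per = np.array(stats.per_copy)
        se = per.std(ddof=1) / np.sqrt(n_copies)
        assert abs(stats.mean_pct - 100 * rate) <= 2 * se
        assert abs(stats.mean_pct - 0.25) <= 0.05
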
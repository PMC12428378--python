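"""Type clustering under the <5% divergence rule and column reconciliation."""

import pytest

from horscan.hor import HORCopy
from horscan.monomer_types import (
    cluster_types,
    pairwise_divergence,
    reconcile_types_with_columns,
)

from conftest import mutate


class TestPairwiseDivergence:
    def test_identical_sequences(self, consensus):
        assert pairwise_divergence(consensus.sequence, consensus.sequence) == 0.0

    @pytest.mark.parametrize("n_subs,expected", [(8, 8 / 171), (9, 9 / 171)])
    def test_substitution_counts(self, consensus, n_subs, expected):
        # 8/171 is just under the 5% type threshold, 9/171 just over
        other = mutate(consensus.sequence, list(range(5, 5 + 17 * n_subs, 17)))
        assert pairwise_divergence(consensus.sequence, other) == pytest.approx(expected)

    def test_symmetry_and_indel(self):
        a, b = "ACGTACGTAC", "ACGTCGTAC"  # one deletion
        assert pairwise_divergence(a, b) == pairwise_divergence(b, a) == 1 / 10

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_divergence("", "ACGT")


class TestClusterTypes:
    def test_identical_monomers_form_one_type(self, consensus):
        asg = cluster_types([consensus.sequence] * 5)
        assert asg.n_types == 1
        assert set(asg.types.values()) == {1}

    def test_divergence_above_threshold_splits(self, consensus):
        a = consensus.sequence
        b = mutate(a, list(range(0, 169, 12))[:14])  # ~8.2% apart
        asg = cluster_types([a, b])
        assert asg.n_types == 2

    @pytest.mark.parametrize(
        "n_subs,n_types", [(5, 1), (12, 2)], ids=["3pct-merges", "7pct-splits"]
    )
    def test_threshold_sharpness(self, consensus, n_subs, n_types):
        # planted two-type arrays at ~3% vs ~7% inter-type divergence, no copy noise
        a = consensus.sequence
        b = mutate(a, list(range(3, 3 + 13 * n_subs, 13))[:n_subs])
        asg = cluster_types([a, b] * 10)
        assert asg.n_types == n_types

    def test_type_ids_dense_by_first_occurrence(self, consensus):
        a = consensus.sequence
        b = mutate(a, list(range(0, 168, 9)))
        c = mutate(a, list(range(1, 168, 9)))
        asg = cluster_types([b, a, c, b])
        assert asg.types == {1: 1, 2: 2, 3: 3, 4: 1}

    def test_determinism(self, consensus):
        seqs = [mutate(consensus.sequence, [(i * 7) % 171, (i * 11 + 3) % 171]) for i in range(30)]
        a1 = cluster_types(seqs)
        a2 = cluster_types(seqs)
        assert a1.types == a2.types and a1.centroids == a2.centroids

    def test_planted_library_recovered_exactly(self, consensus):
        from horscan.synth import make_type_library

        lib = make_type_library(12, consensus, inter_type_div=0.15, rng_seed=3)
        seqs = [lib[i % 12] for i in range(120)]
        asg = cluster_types(seqs)
        assert asg.n_types == 12


def _make_copies(type_seqs, seq_lookup):
    copies = []
    enum = 1
    for ts in type_seqs:
        copies.append(
            HORCopy(
                start_enum=enum,
                type_seq=list(ts),
                monomer_seqs=[seq_lookup[t] for t in ts],
                label="",
                col_map=list(range(len(ts))),
            )
        )
        enum += len(ts)
    return copies


class TestReconcileWithColumns:
    @pytest.fixture()
    def borderline_setup(self, consensus):
        # A and B differ at 16 positions (9.4%, distinct types); m sits at
        # 8/171 = 4.68% from both.
        a = consensus.sequence
        sites = list(range(2, 2 + 16 * 10, 10))
        b = mutate(a, sites)
        m = mutate(a, sites[:8])
        return a, b, m

    def test_column_consistent_assignment_unchanged(self, consensus):
        a = consensus.sequence
        b = mutate(a, list(range(0, 160, 8)))
        copies = _make_copies([[1, 2]] * 3, {1: a, 2: b})
        asg = cluster_types([a, b] * 3)
        out = reconcile_types_with_columns(asg, copies)
        assert out.types == asg.types

    def test_borderline_monomer_reassigned_to_column_majority(self, borderline_setup):
        a, b, m = borderline_setup
        # enumeration order b, m, a, a, a: m greedily joins the B-founded
        # type (4.7% away), but the column majority is the A type, also
        # within the threshold of m
        asg = cluster_types([b, m, a, a, a])
        assert asg.types[2] == asg.types[1] != asg.types[3]
        copies = [
            HORCopy(i, [asg.types[i]], [s], col_map=[0])
            for i, s in enumerate([b, m, a, a, a], 1)
        ]
        out = reconcile_types_with_columns(asg, copies)
        assert out.types[2] == out.types[3]  # m moved to the majority type
        assert out.types[1] != out.types[3]  # b itself is too far to move

    def test_far_monomer_keeps_its_type(self, consensus):
        a = consensus.sequence
        far = mutate(a, list(range(4, 4 + 12 * 13, 13)))  # ~7% away
        asg = cluster_types([a, a, far])
        copies = [
            HORCopy(1, [1], [a], col_map=[0]),
            HORCopy(2, [1], [a], col_map=[0]),
            HORCopy(3, [2], [far], col_map=[0]),
        ]
        out = reconcile_types_with_columns(asg, copies)
        assert out.types[3] != out.types[1]

    def test_idempotence(self, borderline_setup):
        a, b, m = borderline_setup
        asg = cluster_types([a, a, a, b, m])
        copies = [HORCopy(i, [asg.types[i]], [s], col_map=[0]) for i, s in enumerate([a, a, a, b, m], 1)]
        once = reconcile_types_with_columns(asg, copies)
        copies2 = [HORCopy(i, [once.types[i]], [s], col_map=[0]) for i, s in enumerate([a, a, a, b, m], 1)]
        twice = reconcile_types_with_columns(once, copies2)
        assert twice.types == once.types
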
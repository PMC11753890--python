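import numpy as np
import pytest

from oracles import brute_ctd
from targetclp.io_formats import AA_ORDER, ProteinRecord
from targetclp.qlc_features import (
    PROPERTY_ORDER,
    QLC_DIM,
    QLCNormalizer,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    encode_groups,
    fit_apply_normalization,
    load_groupings,
    qlc_vector,
)

GROUPS = load_groupings()


class TestGroupings:
    def test_each_property_partitions_the_alphabet(self):
        for prop in PROPERTY_ORDER:
            members = "".join(GROUPS[prop].values())
            assert sorted(members) == sorted(AA_ORDER)

    def test_encode_constant_for_homopolymer(self):
        rec = ProteinRecord("p", "AAAA")
        for prop in PROPERTY_ORDER:
            encoded = encode_groups(rec, GROUPS[prop])
            assert len(set(encoded)) == 1

    def test_charge_grouping_lookup(self):
        # A is charge-neutral (group 2), R is positive (group 1)
        assert encode_groups(ProteinRecord("p", "AR"), GROUPS["charge"]) == "21"

    def test_random_sequence_matches_table_lookup(self, rng):
        seq = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=25))
        for prop in PROPERTY_ORDER:
            encoded = encode_groups(ProteinRecord("p", seq), GROUPS[prop])
            lookup = {aa: g for g, aas in GROUPS[prop].items() for aa in aas}
            assert encoded == "".join(lookup[ch] for ch in seq)

    def test_x_excluded_with_adjusted_length(self):
        enc = encode_groups(ProteinRecord("p", "AXA"), GROUPS["charge"])
        assert enc == "22"

    def test_all_x_rejected(self):
        with pytest.raises(ValueError, match="no resolvable"):
            encode_groups(ProteinRecord("p", "XX"), GROUPS["charge"])


class TestCTDIndices:
    def test_composition_cases(self):
        np.testing.assert_allclose(ctd_composition("111"), (100, 0, 0))
        np.testing.assert_allclose(ctd_composition("1212"), (50, 50, 0))

    def test_composition_sums_to_100(self, rng):
        for _ in range(20):
            s = "".join(rng.choice(list("123"), size=int(rng.integers(2, 40))))
            assert ctd_composition(s).sum() == pytest.approx(100, abs=1e-9)

    def test_transition_alternating(self):
        # "1212": 3 adjacent pairs, all of them 1<->2 boundaries
        np.testing.assert_allclose(ctd_transition("1212"), (100, 0, 0))

    def test_transition_homogeneous_zero(self):
        np.testing.assert_allclose(ctd_transition("1111"), (0, 0, 0))

    def test_transition_bounded_by_100(self, rng):
        for _ in range(20):
            s = "".join(rng.choice(list("123"), size=int(rng.integers(2, 40))))
            assert ctd_transition(s).sum() <= 100 + 1e-9

    def test_distribution_uniform_group(self):
        expected = [25, 25, 50, 75, 100] + [0] * 10
        np.testing.assert_allclose(ctd_distribution("1111"), expected)

    def test_distribution_absent_group_zero(self):
        d = ctd_distribution("1212")
        np.testing.assert_allclose(d[10:], np.zeros(5))

    def test_distribution_monotone_in_range(self, rng):
        for _ in range(20):
            s = "".join(rng.choice(list("123"), size=int(rng.integers(3, 50))))
            d = ctd_distribution(s)
            assert ((0 <= d) & (d <= 100)).all()
            for g in range(3):
                chunk = d[5 * g : 5 * g + 5]
                if chunk.any():
                    assert (np.diff(chunk) >= -1e-12).all()

    def test_indices_match_brute_force(self, rng):
        for _ in range(10):
            s = "".join(rng.choice(list("123"), size=int(rng.integers(4, 60))))
            c, t, d = brute_ctd(s)
            np.testing.assert_allclose(ctd_composition(s), c)
            np.testing.assert_allclose(ctd_transition(s), t)
            np.testing.assert_allclose(ctd_distribution(s), d)


class TestQLCVector:
    def test_dimension_147(self, records):
        for rec in records:
            assert qlc_vector(rec).shape == (QLC_DIM,)

    def test_homopolymer_transitions_zero(self):
        vec = qlc_vector(ProteinRecord("p", "A" * 30))
        for p in range(7):
            t_part = vec[21 * p + 3 : 21 * p + 6]
            np.testing.assert_allclose(t_part, 0)

    def test_matches_per_index_recomputation(self, rng):
        seq = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=40))
        rec = ProteinRecord("p", seq)
        vec = qlc_vector(rec)
        for p, prop in enumerate(PROPERTY_ORDER):
            encoded = encode_groups(rec, GROUPS[prop])
            c, t, d = brute_ctd(encoded)
            np.testing.assert_allclose(vec[21 * p : 21 * p + 3], c)
            np.testing.assert_allclose(vec[21 * p + 3 : 21 * p + 6], t)
            np.testing.assert_allclose(vec[21 * p + 6 : 21 * p + 21], d)

    def test_composition_invariant_under_reversal(self, rng):
        seq = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=31))
        fwd = qlc_vector(ProteinRecord("p", seq))
        rev = qlc_vector(ProteinRecord("p", seq[::-1]))
        for p in range(7):
            np.testing.assert_allclose(fwd[21 * p : 21 * p + 3], rev[21 * p : 21 * p + 3])
        # distribution is generally direction-dependent
        assert not np.allclose(fwd, rev)


class TestNormalization:
    def test_two_point_column_closed_form(self):
        norm = QLCNormalizer().fit(np.array([[0.0], [10.0]]))
        z = norm.transform(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(z.ravel(), [-0.7071067811865475, 0.7071067811865475])

    def test_constant_column_maps_to_zero_and_flagged(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        norm = QLCNormalizer().fit(X)
        assert norm.constant_mask_.tolist() == [True, False]
        assert (norm.transform(X)[:, 0] == 0).all()

    def test_fit_then_apply_centers_training_columns(self, rng):
        X = rng.normal(size=(30, 10)) * 5 + 2
        table_z = QLCNormalizer().fit(X).transform(X)
        np.testing.assert_allclose(table_z.mean(axis=0), 0, atol=1e-9)

    def test_apply_without_fit_rejected(self, rng):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            QLCNormalizer().transform(rng.normal(size=(3, 2)))

    def test_minmax_mode(self, rng):
        X = rng.normal(size=(20, 4))
        z = QLCNormalizer(mode="minmax").fit(X).transform(X)
        np.testing.assert_allclose(z.min(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.max(axis=0), 1, atol=1e-12)

    def test_fit_apply_wrapper_roundtrip(self, rng):
        from targetclp.io_formats import FeatureTable

        X = rng.normal(size=(8, 5))
        table = FeatureTable([f"s{i}" for i in range(8)], ["QLC"], [5], X)
        normed, stats = fit_apply_normalization(table)
        normed2, _ = fit_apply_normalization(table, stats)
        np.testing.assert_array_equal(normed.matrix, normed2.matrix)
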
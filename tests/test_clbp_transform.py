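import numpy as np
import pytest

from oracles import brute_code_maps, brute_descriptor, brute_scale
from targetclp.clbp_transform import (
    SCHEME,
    build_recm_t,
    clbp_code_maps,
    clbp_histogram,
    pssm_clbp,
    recm_clbp,
    scale_to_image,
)
from targetclp.io_formats import AA_ORDER, ProfileMatrix, ProteinRecord
from targetclp.synthetic_data import gen_profile, gen_sequences, SynthSpec


def random_profile(length, rng):
    return ProfileMatrix(rng.integers(-15, 16, size=(length, 20)).astype(float))


class TestScaleToImage:
    def test_endpoints(self, rng):
        m = rng.uniform(-7, 9, size=(5, 20))
        m[0, 0], m[1, 1] = -7.0, 9.0
        img = scale_to_image(ProfileMatrix(m))
        assert img[0, 0] == 0 and img[1, 1] == 255
        assert img.min() >= 0 and img.max() <= 255

    def test_constant_matrix_all_zero(self):
        img = scale_to_image(ProfileMatrix(np.full((4, 20), 3.0)))
        assert (img == 0).all()

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(10, 20))
        np.testing.assert_array_equal(
            scale_to_image(x), scale_to_image(1.7 * x + 3.2)
        )

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(6, 20))
        np.testing.assert_array_equal(scale_to_image(x), brute_scale(x))


class TestCodeMaps:
    def test_constant_image_all_comparisons_at_equality(self):
        maps = clbp_code_maps(np.full((5, 20), 100))
        assert (maps.c_map == 1).all()
        assert (maps.s_map == 255).all()
        assert (maps.m_map == 255).all()

    def test_center_count(self, rng):
        for length in (3, 7, 30):
            img = rng.integers(0, 256, size=(length, 20))
            assert clbp_code_maps(img).n_centers == (length - 2) * 18

    def test_matches_brute_force(self, rng):
        img = np.random.default_rng(11).integers(0, 256, size=(6, 20))
        maps = clbp_code_maps(img)
        c, s, m = brute_code_maps(img)
        np.testing.assert_array_equal(maps.c_map, c)
        np.testing.assert_array_equal(maps.s_map, s)
        np.testing.assert_array_equal(maps.m_map, m)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="too short"):
            clbp_code_maps(rng.integers(0, 256, size=(2, 20)))


class TestHistogram:
    def test_constant_image_mass_in_uniform_255_bin(self):
        maps = clbp_code_maps(np.full((6, 20), 42))
        desc = clbp_histogram(maps)
        s_part = desc.vector[:59]
        # code 255 has zero transitions -> the last (58th) uniform bin
        assert s_part[57] == maps.n_centers
        assert s_part.sum() == maps.n_centers
        assert (s_part > 0).sum() == 1

    def test_descriptor_length_and_masses(self, rng):
        img = rng.integers(0, 256, size=(8, 20))
        maps = clbp_code_maps(img)
        desc = clbp_histogram(maps)
        assert desc.vector.shape == (236,)
        assert desc.scheme == SCHEME
        n = maps.n_centers
        assert desc.vector[:59].sum() == n          # S part
        assert desc.vector[59:118].sum() == n       # M part
        assert desc.vector[118:].sum() == n         # joint M x C part

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(8, 20))
        np.testing.assert_array_equal(pssm_clbp(ProfileMatrix(m)).vector, brute_descriptor(m))

    def test_normalized_flag(self, rng):
        img = rng.integers(0, 256, size=(5, 20))
        maps = clbp_code_maps(img)
        desc = clbp_histogram(maps, normalize=True)
        assert desc.vector[:59].sum() == pytest.approx(1.0)


class TestPssmClbp:
    def test_oracle_equivalence_many_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            length = int(rng.integers(3, 61))
            m = rng.normal(scale=rng.uniform(0.5, 8), size=(length, 20))
            np.testing.assert_array_equal(
                pssm_clbp(ProfileMatrix(m)).vector, brute_descriptor(m)
            )

    def test_affine_invariance_of_descriptor(self, rng):
        prof = random_profile(15, rng)
        shifted = ProfileMatrix(2.0 * prof.values + 5.0)
        np.testing.assert_array_equal(
            pssm_clbp(prof).vector, pssm_clbp(shifted).vector
        )

    @pytest.mark.parametrize("length", [3, 10, 500])
    def test_dimension_always_236(self, length, rng):
        assert pssm_clbp(random_profile(length, rng)).vector.shape == (236,)

    def test_deterministic(self):
        rec = gen_sequences(SynthSpec(n_sequences=1, length_range=(50, 50), seed=1))[0]
        prof = gen_profile(rec, seed=1)
        np.testing.assert_array_equal(pssm_clbp(prof).vector, pssm_clbp(prof).vector)


class TestRecmT:
    def test_homopolymer_rows_equal_residue_row(self, energy_matrix):
        rt = build_recm_t(ProteinRecord("p", "AA"), energy_matrix)
        np.testing.assert_array_equal(rt.values[0], energy_matrix.values[0])
        np.testing.assert_array_equal(rt.values[1], energy_matrix.values[0])

    def test_rows_follow_sequence(self, energy_matrix):
        rt = build_recm_t(ProteinRecord("p", "ARN"), energy_matrix)
        for j, res in enumerate("ARN"):
            np.testing.assert_array_equal(
                rt.values[j], energy_matrix.values[AA_ORDER.index(res)]
            )

    def test_random_probes(self, energy_matrix, rng):
        seq = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=30))
        rt = build_recm_t(ProteinRecord("p", seq), energy_matrix)
        for _ in range(50):
            j = int(rng.integers(30))
            l = int(rng.integers(20))
            assert rt.values[j, l] == energy_matrix.values[AA_ORDER.index(seq[j]), l]

    def test_x_policy_row(self, energy_matrix):
        rt = build_recm_t(ProteinRecord("p", "AXA"), energy_matrix)
        np.testing.assert_allclose(rt.values[1], energy_matrix.values.mean(axis=0))


class TestRecmClbp:
    def test_dimension_236(self, energy_matrix, records):
        for rec in records[:3]:
            assert recm_clbp(rec, energy_matrix).vector.shape == (236,)

    def test_homopolymer_matches_brute_force(self, energy_matrix):
        rec = ProteinRecord("homo", "A" * 20)
        rt = build_recm_t(rec, energy_matrix)
        assert (rt.values == rt.values[0]).all()
        np.testing.assert_array_equal(
            recm_clbp(rec, energy_matrix).vector, brute_descriptor(rt.values)
        )

    def test_deterministic(self, energy_matrix, records):
        a = recm_clbp(records[0], energy_matrix).vector
        b = recm_clbp(records[0], energy_matrix).vector
        np.testing.assert_array_equal(a, b)
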
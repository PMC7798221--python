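"""Relation matrix accumulation, transformation chain and container I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import WORKED_SET, brute_corm, brute_pmi, random_binary_set
from fip.featurize import FeaturizeError, vectors_from_matrix
from fip.relmat import (
    DegenerateProfileError,
    RelationMatrixError,
    accumulate_corm,
    corm_to_coprm,
    coprm_to_pmirm,
    load_matrix,
    merge_corms,
    pmirm_to_zpmirm,
    save_matrix,
    transform,
)
from fip.synthdata import SyntheticDesign, generate, synthetic_spec


def _vecs(mat):
    return vectors_from_matrix(mat, synthetic_spec(mat.shape[1]))


class TestAccumulateCorm:
    def test_worked_example(self, worked_chain):
        corm = worked_chain[0]
        assert corm.values.tolist() == [[3, 2, 1], [2, 2, 0], [1, 0, 2]]
        assert corm.set_size == 4

    def test_single_vector_is_its_own_outer_product(self):
        corm = accumulate_corm(_vecs(np.array([[1, 0, 1]], dtype=np.uint8)))
        assert corm.values.tolist() == [[1, 0, 1], [0, 0, 0], [1, 0, 1]]

    def test_all_zero_vectors_give_zero_matrix(self):
        corm = accumulate_corm(_vecs(np.zeros((3, 4), dtype=np.uint8)))
        assert not corm.values.any() and corm.set_size == 3

    def test_empty_stream_is_an_error(self):
        with pytest.raises(FeaturizeError, match="empty"):
            accumulate_corm([])

    def test_mixed_specs_refused(self):
        a = _vecs(np.ones((1, 3), dtype=np.uint8))
        b = vectors_from_matrix(np.ones((1, 4), dtype=np.uint8), synthetic_spec(4))
        with pytest.raises(FeaturizeError, match="mixed"):
            accumulate_corm(a + b)

    def test_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            mat = random_binary_set(rng)
            assert np.array_equal(
                accumulate_corm(_vecs(mat)).values, brute_corm(mat)
            )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        mat = random_binary_set(rng)
        shuffled = mat[rng.permutation(mat.shape[0])]
        assert np.array_equal(
            accumulate_corm(_vecs(mat)).values,
            accumulate_corm(_vecs(shuffled)).values,
        )


class TestMergeCorms:
    def test_merge_equals_accumulation_over_concatenation(self):
        rng = np.random.default_rng(3)
        d = 8
        m1 = (rng.random((20, d)) < 0.4).astype(np.uint8)
        m2 = (rng.random((11, d)) < 0.6).astype(np.uint8)
        merged = merge_corms(accumulate_corm(_vecs(m1)), accumulate_corm(_vecs(m2)))
        joint = accumulate_corm(_vecs(np.vstack([m1, m2])))
        assert np.array_equal(merged.values, joint.values)
        assert merged.set_size == 31

    def test_merge_with_zero_matrix_is_identity_and_commutative(self):
        rng = np.random.default_rng(4)
        mat = random_binary_set(rng, max_d=6)
        a = accumulate_corm(_vecs(mat))
        z = accumulate_corm(_vecs(np.zeros((2, mat.shape[1]), dtype=np.uint8)))
        ab = merge_corms(a, z)
        ba = merge_corms(z, a)
        assert np.array_equal(ab.values, a.values)
        assert np.array_equal(ab.values, ba.values)

    def test_spec_mismatch_refused(self):
        a = accumulate_corm(_vecs(np.ones((1, 3), dtype=np.uint8)))
        b = accumulate_corm(_vecs(np.ones((1, 4), dtype=np.uint8)))
        with pytest.raises(RelationMatrixError, match="spec"):
            merge_corms(a, b)


class TestTransformChain:
    def test_worked_coprm(self, worked_chain):
        coprm = worked_chain[1]
        assert np.allclose(
            coprm.values, [[0.75, 0.5, 0.25], [0.5, 0.5, 0.0], [0.25, 0.0, 0.5]]
        )

    def test_worked_pmirm_values_and_mask(self, worked_chain):
        pmirm = worked_chain[2]
        assert pmirm.values[0, 1] == pytest.approx(brute_pmi(0.5, 0.75, 0.5))
        assert pmirm.values[0, 2] == pytest.approx(brute_pmi(0.25, 0.75, 0.5))
        assert not pmirm.defined_mask[1, 2]  # never co-occurring pair
        assert np.isnan(pmirm.values[1, 2])
        assert np.all(np.diag(pmirm.values) == 0)  # observed-feature diagonal

    def test_worked_zpmirm(self, worked_chain):
        z = worked_chain[3]
        mu, sigma = z.standardization_stats
        assert mu == pytest.approx((np.log2(4 / 3) + np.log2(2 / 3)) / 2)
        assert sigma == pytest.approx(0.5)
        assert z.values[0, 1] == pytest.approx(1.0)
        assert z.values[0, 2] == pytest.approx(-1.0)
        assert z.values[0, 0] == pytest.approx(-mu / sigma)

    def test_ubiquitous_feature_has_unit_probability_and_zero_pmi(self):
        mat = np.ones((5, 2), dtype=np.uint8)
        coprm = corm_to_coprm(accumulate_corm(_vecs(mat)))
        assert np.all(coprm.values == 1.0)
        pmirm = coprm_to_pmirm(coprm)
        assert pmirm.values[0, 1] == 0.0  # p(x,y)=p(x)=p(y)=1

    def test_twice_expected_cooccurrence_gives_pmi_one(self):
        mat = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.uint8)
        pmirm = transform(accumulate_corm(_vecs(mat)), "pmirm")
        assert pmirm.values[0, 1] == pytest.approx(1.0)

    def test_never_observed_feature_is_fully_undefined(self):
        mat = np.array([[1, 0, 1], [1, 0, 0]], dtype=np.uint8)
        pmirm = transform(accumulate_corm(_vecs(mat)), "pmirm")
        assert not pmirm.defined_mask[1, 1]
        assert not pmirm.defined_mask[0, 1]
        assert np.isnan(pmirm.values[1, 1])

    def test_zero_set_size_cannot_be_normalized(self, worked_chain):
        corm = worked_chain[0]
        corm.set_size = 0
        with pytest.raises(RelationMatrixError):
            corm_to_coprm(corm)

    def test_constant_profile_is_degenerate(self):
        # two feature pairs, both with identical PMI = 1; cross pairs
        # never co-occur, so the defined profile is constant: sigma = 0
        mat = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=np.uint8
        )
        pmirm = transform(accumulate_corm(_vecs(mat)), "pmirm")
        offdiag = pmirm.defined_offdiag_values()
        assert np.allclose(offdiag, offdiag[0])
        with pytest.raises(DegenerateProfileError):
            pmirm_to_zpmirm(pmirm)

    def test_duplication_doubles_corm_but_fixes_probabilities(self):
        rng = np.random.default_rng(11)
        mat = (rng.random((30, 6)) < 0.5).astype(np.uint8)
        single = accumulate_corm(_vecs(mat))
        double = accumulate_corm(_vecs(np.vstack([mat, mat])))
        assert np.array_equal(double.values, 2 * single.values)
        p1, p2 = corm_to_coprm(single), corm_to_coprm(double)
        assert np.allclose(p1.values, p2.values)
        m1, m2 = coprm_to_pmirm(p1), coprm_to_pmirm(p2)
        assert np.allclose(m1.values, m2.values, equal_nan=True)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariants_on_random_instances(self, seed):
        """Symmetry, probability bounds, the CORM cell bound and the
        ZPMIRM standardization identity on arbitrary random sets."""
        rng = np.random.default_rng(seed)
        mat = random_binary_set(rng)
        corm = accumulate_corm(_vecs(mat))
        assert np.array_equal(corm.values, corm.values.T)
        diag = np.diag(corm.values)
        assert np.all(corm.values <= np.minimum.outer(diag, diag))
        coprm = corm_to_coprm(corm)
        assert np.all((coprm.values >= 0) & (coprm.values <= 1))
        pmirm = coprm_to_pmirm(coprm)
        offdiag = pmirm.defined_offdiag_values()
        # PMI bound: p_ij <= min(p_ii, p_jj) implies PMI <= -log2(max marginal)
        iu = np.triu_indices(mat.shape[1], k=1)
        pm = pmirm.defined_mask[iu]
        pv = pmirm.values[iu][pm]
        d = np.diag(coprm.values)
        bound = -np.log2(np.maximum.outer(d, d), where=np.maximum.outer(d, d) > 0,
                         out=np.full((mat.shape[1],) * 2, np.inf))
        assert np.all(pv <= bound[iu][pm] + 1e-12)
        if offdiag.size >= 2 and offdiag.std() > 0:
            z = pmirm_to_zpmirm(pmirm)
            zoff = z.defined_offdiag_values()
            assert abs(zoff.mean()) < 1e-9
            assert abs(zoff.std(ddof=0) - 1) < 1e-9


class TestIndependenceLimit:
    def test_independent_features_have_near_zero_pmi(self):
        """Two independent Bernoulli(0.3) features over n=50,000: |PMI| < 0.1
        in at least 99% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            mat = (rng.random((50_000, 2)) < 0.3).astype(np.uint8)
            pmirm = transform(accumulate_corm(_vecs(mat)), "pmirm")
            if abs(pmirm.values[0, 1]) < 0.1:
                hits += 1
        assert hits >= 99


class TestContainerIO:
    def test_corm_round_trip_is_exact(self, worked_chain, tmp_path):
        corm = worked_chain[0]
        path = str(tmp_path / "w.rm")
        save_matrix(corm, path)
        back = load_matrix(path)
        assert np.array_equal(back.values, corm.values)
        assert back.variant == "corm" and back.set_size == 4
        assert back.spec == corm.spec

    def test_zpmirm_round_trip_recovers_stats_and_mask(self, worked_chain, tmp_path):
        z = worked_chain[3]
        path = str(tmp_path / "z.rm")
        save_matrix(z, path)
        back = load_matrix(path)
        assert back.standardization_stats == pytest.approx(z.standardization_stats)
        assert np.array_equal(back.defined_mask, z.defined_mask)
        assert np.allclose(back.values, z.values, atol=1e-12, equal_nan=True)

    def test_corrupted_container_is_refused(self, tmp_path):
        path = tmp_path / "junk.rm"
        path.write_bytes(b"this is not a relation matrix")
        with pytest.raises(RelationMatrixError, match="corrupted"):
            load_matrix(str(path))

    def test_toolkit_mismatch_is_refused(self, worked_chain, tmp_path):
        corm = worked_chain[0]
        path = str(tmp_path / "w.rm")
        save_matrix(corm, path)
        with pytest.raises(RelationMatrixError, match="toolkit"):
            load_matrix(path, expect_toolkit="other-toolkit/9.9")
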
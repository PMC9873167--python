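"""Aitchison-geometry primitives: closure, ilr, means, variation matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skbio.stats.composition as skb

from timeuse_coda import (
    IlrBasis,
    aitchison_distance,
    close,
    compositional_mean,
    ilr,
    ilr_inverse,
    make_pivot_basis,
    random_basis,
    rotated_basis,
    variation_matrix,
)
from timeuse_coda.errors import (
    ConfigurationError,
    EstimationError,
    InvalidCompositionError,
)

positive_parts = st.tuples(
    *[st.floats(min_value=1e-3, max_value=23.0) for _ in range(3)]
)


class TestClose:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((1, 1, 2), (6, 6, 12)),
            ((8, 8, 8), (8, 8, 8)),
            ((0.35, 0.25, 0.40), (8.4, 6.0, 9.6)),
        ],
    )
    def test_proportional_scaling(self, raw, expected):
        np.testing.assert_allclose(close(raw), expected, atol=1e-12)

    def test_sum_is_bit_exact(self, compositions):
        assert all(c.sum() == 24.0 for c in close(compositions * 3.7))

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidCompositionError):
            close((0.0, 0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(InvalidCompositionError):
            close((1.0, -0.5, 2.0))

    def test_zero_part_passes_through(self):
        out = close((0.0, 1.0, 2.0))
        assert out[0] == 0.0 and out.sum() == 24.0


class TestPivotBasis:
    def test_orthonormal_zero_sum(self):
        v = make_pivot_basis().matrix
        np.testing.assert_allclose(v.T @ v, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(v.sum(axis=0), 0.0, atol=1e-12)

    def test_equal_parts_map_to_origin(self):
        for order in (("pa", "sb", "sleep"), ("sleep", "pa", "sb")):
            z = ilr(np.array([8.0, 8.0, 8.0]), make_pivot_basis(order))
            np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_two_orders_differ_by_orthogonal_rotation(self):
        v1 = make_pivot_basis(("pa", "sb", "sleep")).matrix
        v2 = make_pivot_basis(("sleep", "sb", "pa")).matrix
        r = v1.T @ v2
        np.testing.assert_allclose(r.T @ r, np.eye(2), atol=1e-12)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            make_pivot_basis(("pa", "pa", "sleep"))

    def test_non_orthonormal_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            IlrBasis(matrix=np.ones((3, 2)))


class TestIlr:
    def test_known_closed_form(self):
        z = ilr(close((12.0, 6.0, 6.0)), make_pivot_basis())
        np.testing.assert_allclose(z, [np.sqrt(2.0 / 3.0) * np.log(2.0), 0.0], atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(positive_parts)
    def test_round_trip_identity(self, raw):
        c = close(raw)
        back = ilr_inverse(ilr(c), total=24.0)
        np.testing.assert_allclose(back, c, rtol=1e-10)

    def test_zero_part_raises_naming_part(self):
        with pytest.raises(InvalidCompositionError, match="sb"):
            ilr(np.array([5.0, 0.0, 19.0]))

    def test_origin_maps_to_equal_parts(self):
        np.testing.assert_allclose(ilr_inverse(np.zeros(2)), [8.0, 8.0, 8.0], atol=1e-12)

    def test_matches_reference_implementation(self, compositions):
        basis = make_pivot_basis()
        np.testing.assert_allclose(
            ilr(compositions, basis),
            skb.ilr(compositions / compositions.sum(axis=1, keepdims=True), basis=basis.matrix.T),
            atol=1e-10,
        )

    def test_isometry(self, compositions):
        basis = rotated_basis(make_pivot_basis(), angle=0.83)
        z = ilr(compositions, basis)
        for i in range(0, 10):
            d_ilr = np.linalg.norm(z[i] - z[i + 1])
            assert d_ilr == pytest.approx(aitchison_distance(compositions[i], compositions[i + 1]), abs=1e-10)

    def test_basis_invariance_of_inverse(self, compositions, rng):
        """Coordinates taken in any basis invert to the same composition."""
        for _ in range(3):
            b = random_basis(rng)
            np.testing.assert_allclose(
                ilr_inverse(ilr(compositions, b), b), compositions, rtol=1e-10
            )


class TestCompositionalMean:
    def test_mean_of_identical_points(self):
        data = np.tile([6.0, 6.0, 12.0], (4, 1))
        np.testing.assert_allclose(compositional_mean(data), [6, 6, 12], rtol=1e-12)

    def test_dual_formula_equivalence(self, rng):
        """Closed geometric means == inverse-ilr of weighted ilr average."""
        for _ in range(50):
            n = int(rng.integers(3, 40))
            x = close(np.exp(rng.normal(size=(n, 3))))
            w = rng.uniform(0.1, 5.0, size=n)
            b = random_basis(rng)
            via_geo = compositional_mean(x, w)
            via_ilr = ilr_inverse(np.average(ilr(x, b), axis=0, weights=w), b)
            np.testing.assert_allclose(via_geo, via_ilr, rtol=1e-10)

    def test_recovers_logistic_normal_centre(self):
        rng = np.random.default_rng(7)
        centre = close((10.0, 5.0, 9.0))
        b = make_pivot_basis()
        z = ilr(centre, b) + rng.standard_normal((20000, 2)) * 0.6
        est = compositional_mean(ilr_inverse(z, b))
        # MC error on the ilr mean is ~0.6/sqrt(20000) ~ 0.004 -> ~0.03 h
        np.testing.assert_allclose(est, centre, atol=0.1)

    def test_empty_set_rejected(self):
        with pytest.raises(EstimationError):
            compositional_mean(np.empty((0, 3)))


class TestVariationMatrix:
    def test_identical_compositions_give_zero(self):
        vm = variation_matrix(np.tile([8.0, 8.0, 8.0], (5, 1)))
        np.testing.assert_allclose(vm.matrix, 0.0, atol=1e-15)
        assert vm.total_variance == 0.0

    def test_two_point_brute_force(self):
        """Entries equal the weighted sample variance of each pairwise log-ratio."""
        x = np.vstack([close((np.e, 1.0, 1.0)), close((1.0, 1.0, 1.0))])
        w = np.array([0.3, 0.7])
        vm = variation_matrix(x, w)
        # ln(pa/sb) takes values {1, 0}: weighted variance = E[v^2]-E[v]^2
        expected = 0.3 * 1.0 - 0.3**2
        assert vm.matrix[0, 1] == pytest.approx(expected, rel=1e-12)
        assert vm.matrix[0, 2] == pytest.approx(expected, rel=1e-12)
        assert vm.matrix[1, 2] == pytest.approx(0.0, abs=1e-15)
        assert vm.total_variance == pytest.approx(2 * expected, rel=1e-12)

    def test_invariant_to_rescaling(self, compositions, weights):
        a = variation_matrix(compositions, weights)
        b = variation_matrix(compositions * 5.0, weights)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_symmetric_zero_diagonal_nonnegative(self, compositions, weights):
        m = variation_matrix(compositions, weights).matrix
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)
        assert np.all(m >= 0)

    def test_normalised_variant(self, compositions):
        vm = variation_matrix(compositions)
        assert vm.total_variance_normalised == pytest.approx(vm.matrix.sum() / 6.0)

    def test_single_point_rejected(self):
        with pytest.raises(EstimationError):
            variation_matrix(np.array([[8.0, 8.0, 8.0]]))
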
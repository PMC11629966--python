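"""Unit and property tests for the concordance statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mica import (
    StudyData,
    class_moments,
    concordance_matrix,
    gmi,
    gmi_plus,
    mcc,
    min_mcc,
    mi_plus,
    mixture_moments,
)
from mica.core_stats import ConcordanceMatrix

from conftest import random_study


# ---------------------------------------------------------------------------
# moments


class TestClassMoments:
    def test_constant_classes(self):
        s = StudyData([0, 0, 2, 2], [1, 1, 2, 2])
        m = class_moments(s)
        np.testing.assert_allclose(m.mean, [0.0, 2.0])
        np.testing.assert_allclose(m.var, [0.0, 0.0])

    def test_ml_variance_divisor(self):
        # hand evaluation: {1, 3} -> mean 2, ML variance ((1-2)^2+(3-2)^2)/2 = 1
        s = StudyData([1.0, 3.0], [1, 1])
        m = class_moments(s)
        assert m.mean[0] == pytest.approx(2.0)
        assert m.var[0] == pytest.approx(1.0)

    def test_single_sample_class(self):
        s = StudyData([5.0], [1])
        m = class_moments(s)
        assert m.mean[0] == 5.0 and m.var[0] == 0.0

    def test_missing_class_named_in_error(self):
        s = StudyData([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2"):
            class_moments(s, classes=[1, 2])

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            StudyData([1.0, np.nan], [1, 2])

    def test_gene_stacked_broadcast(self, rng):
        s = random_study(rng, n_genes=7)
        m = class_moments(s)
        for g in range(7):
            mg = class_moments(StudyData(s.values[g], s.labels))
            np.testing.assert_allclose(m.mean[g], mg.mean)
            np.testing.assert_allclose(m.var[g], mg.var)


class TestMixtureMoments:
    def test_hand_example_two_point(self):
        s = StudyData([0, 0, 2, 2], [1, 1, 2, 2])
        mix = mixture_moments(class_moments(s))
        assert mix.mean == pytest.approx(1.0)
        assert mix.var == pytest.approx(1.0)  # (0 + 0 + 0 + 4)/2 - 1

    def test_degenerate_identical_classes(self):
        s = StudyData([1.0, 3.0, 1.0, 3.0], [1, 1, 2, 2])
        mix = mixture_moments(class_moments(s))
        assert mix.mean == pytest.approx(2.0)
        assert mix.var == pytest.approx(1.0)  # = within-class variance

    def test_symmetric_means(self):
        s = StudyData([-2.0, 0.0, 0.0, 2.0], [1, 1, 2, 2])
        mix = mixture_moments(class_moments(s))
        assert mix.mean == pytest.approx(0.0)
        assert mix.var == pytest.approx(2.0)  # between 1 + within 1

    def test_negative_weight_rejected(self):
        s = StudyData([0, 0, 2, 2], [1, 1, 2, 2])
        with pytest.raises(ValueError, match="non-negative"):
            mixture_moments(class_moments(s), weights=[-0.5, 1.5])

    def test_variance_dominates_within_component(self, rng):
        s = random_study(rng)
        m = class_moments(s)
        mix = mixture_moments(m)
        assert mix.var >= np.mean(m.var) - 1e-12


# ---------------------------------------------------------------------------
# MCC


class TestMCC:
    def test_identical_patterns(self, two_identical_studies):
        assert mcc(*two_identical_studies) == pytest.approx(1.0)

    def test_swapped_classes_flip_sign(self, two_identical_studies):
        x, _ = two_identical_studies
        y = StudyData([2.0, 2.0, 0.0, 0.0], [1, 1, 2, 2], "Y")
        assert mcc(x, y) == pytest.approx(-1.0)

    def test_flat_class_means_give_zero(self, two_identical_studies):
        x, _ = two_identical_studies
        y = StudyData([1.0, 3.0, 1.0, 3.0], [1, 1, 2, 2], "Y")
        assert mcc(x, y) == pytest.approx(0.0)

    def test_degenerate_study_returns_zero_with_warning(self, two_identical_studies):
        x, _ = two_identical_studies
        y = StudyData([4.0, 4.0, 4.0, 4.0], [1, 1, 2, 2], "Y")
        with pytest.warns(RuntimeWarning, match="constant"):
            assert mcc(x, y) == 0.0

    def test_mismatched_class_sets_rejected(self, two_identical_studies):
        x, _ = two_identical_studies
        y = StudyData([0.0, 1.0], [1, 3], "Y")
        with pytest.raises(ValueError, match="class sets"):
            mcc(x, y)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_one(self, seed):
        r = np.random.default_rng(seed)
        x = random_study(r, n_classes=int(r.integers(2, 5)), n_per_class=int(r.integers(1, 6)))
        y = StudyData(r.standard_normal(x.n_samples), x.labels)
        assert abs(mcc(x, y)) <= 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_affine_invariance_and_sign_flip(self, seed):
        r = np.random.default_rng(seed)
        x = random_study(r)
        y = random_study(r)
        a, b = float(r.uniform(0.1, 5)), float(r.normal())
        base = mcc(x, y)
        scaled = StudyData(a * x.values + b, x.labels)
        flipped = StudyData(-a * x.values + b, x.labels)
        assert mcc(scaled, y) == pytest.approx(base, abs=1e-10)
        assert mcc(flipped, y) == pytest.approx(-base, abs=1e-10)

    def test_self_mcc_is_between_over_total_variance(self, rng):
        """MCC(X, X) equals between-class / (between + within) variance,
        checked against a direct two-pass computation."""
        for _ in range(20):
            x = random_study(rng, n_classes=4, n_per_class=6)
            m = class_moments(x)
            between = np.mean(m.mean**2) - np.mean(m.mean) ** 2
            within = np.mean(m.var)
            assert mcc(x, x) == pytest.approx(between / (between + within), abs=1e-12)

    def test_observed_weights_stay_bounded(self, rng):
        labels = np.array([1, 1, 1, 2, 3, 3])
        for _ in range(50):
            x = StudyData(rng.standard_normal(6), labels)
            y = StudyData(rng.standard_normal(6), labels)
            assert abs(mcc(x, y, weights=None)) <= 1.0
            cm = concordance_matrix([x, y], weights="observed")
            assert abs(cm.rho[0, 1]) <= 1.0


class TestConcordanceMatrix:
    def test_matches_pairwise_mcc(self, rng):
        studies = [random_study(rng, study=str(i)) for i in range(4)]
        cm = concordance_matrix(studies)
        for i in range(4):
            for j in range(4):
                expected = 1.0 if i == j else mcc(studies[i], studies[j])
                assert cm.rho[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, rng):
        studies = [random_study(rng, n_genes=5, study=str(i)) for i in range(3)]
        cm = concordance_matrix(studies)
        np.testing.assert_allclose(cm.rho, np.swapaxes(cm.rho, -1, -2))
        np.testing.assert_allclose(cm.rho[..., range(3), range(3)], 1.0)

    def test_identical_copies_share_self_mcc(self, rng):
        x = random_study(rng)
        studies = [StudyData(x.values, x.labels, str(i)) for i in range(3)]
        cm = concordance_matrix(studies)
        target = mcc(x, x)
        iu, ju = np.triu_indices(3, k=1)
        np.testing.assert_allclose(cm.rho[iu, ju], target)

    def test_noise_study_contributes_zeros(self, two_identical_studies):
        x, y = two_identical_studies
        z = StudyData([1.0, 3.0, 1.0, 3.0], [1, 1, 2, 2], "Z")  # flat class means
        cm = concordance_matrix([x, y, z])
        assert cm.rho[0, 2] == pytest.approx(0.0)
        assert cm.rho[1, 2] == pytest.approx(0.0)

    def test_needs_two_studies(self, rng):
        with pytest.raises(ValueError, match="two studies"):
            concordance_matrix([random_study(rng)])


# ---------------------------------------------------------------------------
# information statistics


def _cm(rho, sigma=None):
    rho = np.asarray(rho, dtype=float)
    S = rho.shape[-1]
    sigma = np.ones(S) if sigma is None else np.asarray(sigma, dtype=float)
    return ConcordanceMatrix(rho=rho, sigma=sigma)


class TestMinMCC:
    def test_definition(self):
        rho = np.array([[1, 0.9, 0.8], [0.9, 1, -0.2], [0.8, -0.2, 1]])
        assert min_mcc(_cm(rho)) == pytest.approx(-0.2)

    def test_all_equal(self):
        rho = np.full((3, 3), 0.5)
        np.fill_diagonal(rho, 1.0)
        assert min_mcc(_cm(rho)) == pytest.approx(0.5)

    def test_two_studies_reduces_to_mcc(self, rng):
        x, y = random_study(rng, study="X"), random_study(rng, study="Y")
        cm = concordance_matrix([x, y])
        assert min_mcc(cm) == pytest.approx(mcc(x, y))


class TestMIPlus:
    @pytest.mark.parametrize(
        "rho,expected",
        [(0.0, 0.0), (-0.7, 0.0), (0.6, 0.2231435513)],
    )
    def test_closed_form(self, rho, expected):
        assert mi_plus(rho) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            mi_plus(1.5)

    def test_boundary_is_large_and_finite(self):
        top = mi_plus(1.0)
        assert np.isfinite(top) and top > mi_plus(1 - 1e-9) > 0

    def test_zero_below_zero_and_increasing_above(self):
        grid = np.linspace(-1, 1, 201)
        vals = mi_plus(grid)
        assert np.all(vals[grid <= 0] == 0)
        pos = vals[grid > 0]
        assert np.all(np.diff(pos) > 0)


class TestGMIPlus:
    def test_all_nonpositive_correlations_give_zero(self):
        rho = np.array([[1, -0.5, 0.0], [-0.5, 1, -0.9], [0.0, -0.9, 1]])
        assert gmi_plus(_cm(rho)) == 0.0

    def test_two_study_reduction_to_mi_plus(self, rng):
        """gMI+ at S=2 equals MI+ of the single pairwise MCC (1e-10)."""
        for _ in range(50):
            x, y = random_study(rng, study="X"), random_study(rng, study="Y")
            cm = concordance_matrix([x, y])
            assert gmi_plus(cm) == pytest.approx(mi_plus(cm.rho[0, 1]), abs=1e-10)

    def test_equicorrelated_closed_form(self):
        # det of 3x3 equicorrelation 0.5 matrix is 0.5
        rho = np.full((3, 3), 0.5)
        np.fill_diagonal(rho, 1.0)
        assert gmi_plus(_cm(rho)) == pytest.approx(-0.5 * np.log(0.5), abs=1e-10)

    def test_degenerate_study_drops_out(self, two_identical_studies):
        """A constant study has zero pairwise MCC and contributes nothing."""
        x, y = two_identical_studies
        z = StudyData([4.0, 4.0, 4.0, 4.0], [1, 1, 2, 2], "Z")
        with pytest.warns(RuntimeWarning):
            cm3 = concordance_matrix([x, y, z])
        cm2 = concordance_matrix([x, y])
        assert gmi_plus(cm3) == pytest.approx(gmi_plus(cm2), abs=1e-9)

    def test_nonnegative_on_random_correlation_matrices(self, rng):
        for _ in range(100):
            a = rng.standard_normal((4, 6))
            cov = a @ a.T + 1e-6 * np.eye(4)
            d = np.sqrt(np.diag(cov))
            rho = cov / np.outer(d, d)
            assert gmi_plus(_cm(rho)) >= 0.0

    def test_repair_handles_truncation_breaking_psd(self):
        # zeroing the negative entry of this PSD matrix breaks positive
        # definiteness; the statistic must still be finite and non-negative
        rho = np.array(
            [[1.0, 0.9, 0.9], [0.9, 1.0, 0.9], [0.9, 0.9, 1.0]]
        )
        rho_bad = rho.copy()
        rho_bad[1, 2] = rho_bad[2, 1] = -0.9
        val = gmi_plus(_cm(rho_bad))
        assert np.isfinite(val) and val >= 0


class TestGMI:
    def test_diagonal_gives_zero(self):
        assert gmi(_cm(np.eye(3))) == pytest.approx(0.0)

    def test_sign_symmetric_at_two_studies(self):
        rho = np.array([[1.0, -0.6], [-0.6, 1.0]])
        assert gmi(_cm(rho)) == pytest.approx(0.2231435513, abs=1e-9)

    def test_equals_gmi_plus_for_nonnegative_rho(self, rng):
        for _ in range(20):
            a = rng.uniform(0.1, 1.0, size=(4, 8))
            cov = a @ a.T  # all entries positive
            d = np.sqrt(np.diag(cov))
            cm = _cm(cov / np.outer(d, d))
            assert gmi(cm) == pytest.approx(gmi_plus(cm), abs=1e-9)

    def test_nonnegative_hadamard(self, rng):
        for _ in range(100):
            a = rng.standard_normal((5, 8))
            cov = a @ a.T + 1e-6 * np.eye(5)
            d = np.sqrt(np.diag(cov))
            assert gmi(_cm(cov / np.outer(d, d))) >= 0.0

    def test_non_positive_definite_rejected(self):
        rho = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, 1.0], [-1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            gmi(_cm(rho))

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError, match="zero mixture variance"):
            gmi(_cm(np.eye(2), sigma=[1.0, 0.0]))
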
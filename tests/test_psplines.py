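"""P-spline engine: basis, difference penalty, 1-D penalized Poisson fit."""

import numpy as np
import pytest
from scipy.optimize import minimize

from snpmix import (
    ConfigError,
    InputError,
    PenaltyConfig,
    RangeError,
    bspline_basis,
    difference_matrix,
    fit_pspline_poisson_1d,
)


def coxdeboor(x, knots, j, k):
    """Independent textbook B-spline recursion (test oracle)."""
    if k == 0:
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    left = 0.0
    if knots[j + k] != knots[j]:
        left = (x - knots[j]) / (knots[j + k] - knots[j]) * coxdeboor(x, knots, j, k - 1)
    right = 0.0
    if knots[j + k + 1] != knots[j + 1]:
        right = (
            (knots[j + k + 1] - x)
            / (knots[j + k + 1] - knots[j + 1])
            * coxdeboor(x, knots, j + 1, k - 1)
        )
    return left + right


class TestBasis:
    def test_advised_size_ten_plus_three(self):
        b = bspline_basis(np.linspace(0, 1, 50), 0, 1, nseg=10, degree=3)
        assert b.n_bases == 13
        assert b.matrix.shape == (50, 13)

    def test_partition_of_unity_and_nonnegativity(self):
        b = bspline_basis(np.linspace(-2, 5, 83), -2, 5, nseg=7)
        assert (b.matrix >= 0).all()
        np.testing.assert_allclose(b.matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_cox_de_boor_recursion(self):
        pts = np.array([0.03, 0.31, 0.5, 0.77, 0.99])
        b = bspline_basis(pts, 0, 1, nseg=5, degree=3)
        expected = np.array(
            [[coxdeboor(x, b.knots, j, 3) for j in range(b.n_bases)] for x in pts]
        )
        np.testing.assert_allclose(b.matrix, expected, atol=1e-12)

    def test_eval_point_outside_domain(self):
        with pytest.raises(RangeError):
            bspline_basis([1.5], 0, 1, nseg=5)


class TestDifferenceMatrix:
    def test_first_differences(self):
        d = difference_matrix(5, 1)
        assert d.shape == (4, 5)
        np.testing.assert_array_equal(d[0], [-1, 1, 0, 0, 0])

    def test_third_differences_annihilate_quadratics(self):
        i = np.arange(9.0)
        quad = 3.0 - 2.0 * i + 0.5 * i**2
        np.testing.assert_allclose(difference_matrix(9, 3) @ quad, 0.0, atol=1e-12)

    def test_composition_of_first_differences(self):
        d1a = difference_matrix(10, 1)
        d1b = difference_matrix(9, 1)
        d1c = difference_matrix(8, 1)
        np.testing.assert_allclose(
            difference_matrix(10, 3), d1c @ d1b @ d1a, atol=1e-12
        )

    def test_too_small(self):
        with pytest.raises(ConfigError):
            difference_matrix(3, 3)


class TestFit1D:
    def test_constant_counts_reproduced(self, basis_1d):
        y = np.full(100, 7.0)
        fit = fit_pspline_poisson_1d(y, basis_1d, PenaltyConfig(lam=50.0))
        np.testing.assert_allclose(fit.mu, 7.0, rtol=1e-6)

    @pytest.mark.parametrize("lam", [0.1, 10.0, 1000.0])
    def test_moment_conservation(self, gauss_counts_1d, basis_1d, lam):
        """Third-order penalties conserve total, mean and variance."""
        y, mid = gauss_counts_1d
        fit = fit_pspline_poisson_1d(y, basis_1d, PenaltyConfig(lam=lam), tol=1e-8)
        for q in range(3):
            lhs = float(np.sum(mid**q * fit.mu))
            rhs = float(np.sum(mid**q * y))
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_matches_direct_optimizer(self, gauss_counts_1d, basis_1d):
        """IRLS fixed point equals the penalized-likelihood maximum found by
        a generic quasi-Newton optimizer on the 13-parameter problem."""
        y, _ = gauss_counts_1d
        pen = PenaltyConfig(lam=10.0)
        fit = fit_pspline_poisson_1d(y, basis_1d, pen, tol=1e-10)

        b = basis_1d.matrix
        d = np.diff(np.eye(basis_1d.n_bases), n=3, axis=0)
        ridge = 1e-9 * np.eye(basis_1d.n_bases)

        def negloglik(alpha):
            eta = b @ alpha
            mu = np.exp(eta)
            pen_val = 0.5 * pen.lam * np.sum((d @ alpha) ** 2)
            pen_val += 0.5 * alpha @ ridge @ alpha
            return -(np.sum(y * eta - mu) - pen_val)

        def grad(alpha):
            mu = np.exp(b @ alpha)
            return -(b.T @ (y - mu) - pen.lam * (d.T @ (d @ alpha)) - ridge @ alpha)

        res = minimize(
            negloglik, np.log(y.mean()) * np.ones(basis_1d.n_bases),
            jac=grad, method="BFGS",
            options={"gtol": 1e-10, "maxiter": 2000},
        )
        np.testing.assert_allclose(fit.alpha, res.x, atol=1e-6)

    def test_converges_quickly_on_unimodal_counts(self, gauss_counts_1d, basis_1d):
        y, _ = gauss_counts_1d
        fit = fit_pspline_poisson_1d(y, basis_1d, PenaltyConfig(lam=10.0))
        assert fit.converged
        assert fit.iterations < 10

    def test_fractional_counts_accepted(self, basis_1d):
        rng = np.random.default_rng(2)
        y = rng.gamma(2.0, 3.0, 100)  # fractional pseudo-counts
        fit = fit_pspline_poisson_1d(y, basis_1d, PenaltyConfig(lam=10.0))
        assert fit.converged
        assert fit.mu.sum() == pytest.approx(y.sum(), rel=1e-6)

    def test_all_zero_counts_rejected(self, basis_1d):
        with pytest.raises(InputError):
            fit_pspline_poisson_1d(np.zeros(100), basis_1d, PenaltyConfig())

    def test_mu_positive_everywhere(self, gauss_counts_1d, basis_1d):
        y, _ = gauss_counts_1d
        fit = fit_pspline_poisson_1d(y, basis_1d, PenaltyConfig(lam=10.0))
        assert (fit.mu > 0).all()
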
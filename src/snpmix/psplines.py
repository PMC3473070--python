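"""Penalized Poisson log-density smoothing with B-splines (P-splines).

The log of the expected histogram counts is modelled as a sum of cubic
B-splines on equally spaced knots, and the Poisson log-likelihood is
penalized by the squared third-order differences of the spline
coefficients, scaled by a smoothing parameter lambda.  Two properties of
the third-order penalty make it the right choice for mixture components:

* conservation of moments — at the optimum the fitted density reproduces
  the total count, mean and variance of the data exactly, for every
  lambda, so smoothing never inflates the spread of a component;
* the log-concave limit — as lambda grows the coefficient vector tends to
  a quadratic series (third differences of a quadratic vanish), so the
  fitted density approaches a Gaussian shape while remaining free to
  adapt at moderate lambda.

The 1-D fitter is the documented building block; the 2-D fitter is the
production engine for the mixture.  It uses tensor products of two 1-D
bases and solves the iteratively reweighted least squares (IRLS) system
with array-structured linear algebra (the GLAM scheme): the Kronecker
design matrix is never materialized.  ``naive_fit_2d_kron`` is the slow
explicit-Kronecker formulation, kept as an independent cross-check.

Counts may be fractional: the EM layer hands each component fractional
pseudo-counts, and the Poisson log-likelihood is then read as a
quasi-likelihood in y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ConfigError, InputError, RangeError

#: floor on expected counts inside IRLS; prevents division blow-ups in
#: near-empty regions of the histogram
MU_FLOOR = 1e-10

#: small ridge added to every IRLS system for conditioning where all
#: working weights are near the floor
RIDGE = 1e-9

#: largest n_bases_row * n_bases_col the naive Kronecker path accepts
NAIVE_SIZE_LIMIT = 400


@dataclass(frozen=True)
class BSplineBasis:
    """Equally spaced B-spline basis evaluated at fixed points.

    ``nseg`` equal segments on [lo, hi] plus ``degree`` extra boundary
    splines give ``nseg + degree`` basis functions (the advised default
    is 10 + 3 cubic B-splines).  Rows of ``matrix`` sum to one
    (partition of unity).
    """

    lo: float
    hi: float
    nseg: int
    degree: int
    knots: np.ndarray
    eval_points: np.ndarray
    matrix: np.ndarray  # (n_points, n_bases)

    @property
    def n_bases(self) -> int:
        return self.nseg + self.degree


@dataclass(frozen=True)
class PenaltyConfig:
    """Difference penalty: order (default 3) and smoothing parameter(s).

    ``lam`` applies to the row direction in 2-D; ``lam_c`` defaults to
    the same value (one lambda shared by both directions).
    """

    order: int = 3
    lam: float = 10.0
    lam_c: float | None = None

    def __post_init__(self):
        if self.order < 1:
            raise ConfigError("penalty order must be >= 1")
        if self.lam < 0 or (self.lam_c is not None and self.lam_c < 0):
            raise ConfigError("lambda must be >= 0")

    @property
    def lam_r(self) -> float:
        return self.lam

    @property
    def lam_col(self) -> float:
        return self.lam if self.lam_c is None else self.lam_c


@dataclass
class SmoothFit1D:
    alpha: np.ndarray  # spline coefficients
    eta: np.ndarray  # linear predictor = basis @ alpha (log expected counts)
    mu: np.ndarray  # expected counts = exp(eta)
    iterations: int
    converged: bool
    penalized_loglik: float


@dataclass
class SmoothFit2D:
    coef: np.ndarray  # (n_r, n_c) coefficient matrix
    eta: np.ndarray  # (nx, ny) linear predictor
    mu: np.ndarray  # (nx, ny) expected counts
    iterations: int
    converged: bool
    penalized_loglik: float


def bspline_basis(
    eval_points, lo: float, hi: float, nseg: int = 10, degree: int = 3
) -> BSplineBasis:
    """Cubic B-spline basis on equally spaced knots, extended at the
    boundaries, evaluated at the given points (typically bin midpoints)."""
    if not lo < hi:
        raise ConfigError(f"need lo < hi, got ({lo}, {hi})")
    if nseg < 4:
        raise ConfigError(f"nseg must be >= 4, got {nseg}")
    x = np.asarray(eval_points, float)
    if np.any(x < lo) or np.any(x > hi):
        raise RangeError("eval points outside [lo, hi]")
    h = (hi - lo) / nseg
    knots = lo + h * np.arange(-degree, nseg + degree + 1)
    dm = BSpline.design_matrix(x, knots, degree, extrapolate=False)
    return BSplineBasis(
        lo=lo, hi=hi, nseg=nseg, degree=degree,
        knots=knots, eval_points=x, matrix=dm.toarray(),
    )


def difference_matrix(n: int, order: int = 3) -> np.ndarray:
    """(n - order) x n matrix applying order-th differences to a vector.

    Third differences annihilate quadratic sequences, which is what makes
    the penalty's large-lambda limit log-concave.
    """
    if n <= order:
        raise ConfigError(f"need n > order, got n={n}, order={order}")
    return np.diff(np.eye(n), n=order, axis=0)


def _init_alpha(design_inner, design_rhs, penalty, n):
    """Starting coefficients: penalized least squares of log(y + 1) on the
    basis, with an extra ridge for first-iteration stability."""
    m = design_inner + penalty + 1e-4 * np.eye(n)
    return np.linalg.solve(m, design_rhs)


def _penalty_value_1d(alpha, d, lam):
    return 0.5 * lam * float(np.sum((d @ alpha) ** 2))


#: clip on the linear predictor before exponentiation; never binds at a
#: sensible fit (|eta| stays far below this) but keeps diverging trial
#: steps finite so the line search can reject them
ETA_CLIP = 700.0


def _safe_mu(eta):
    return np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))


def _irls(yv, alpha, eta_of, system_of, pen_value, tol, maxit):
    """Shared IRLS driver for all three fitters.

    At each iteration the penalized Fisher-scoring system is solved, then
    the step is halved until the penalized log-likelihood does not
    decrease (the scoring direction is an ascent direction, so this
    always terminates).  Convergence: max abs coefficient change < tol,
    or the objective change falls below 1e-11 relative — the latter
    catches fits whose coefficients chatter at solver precision in flat
    directions (vast empty histogram regions) while the objective and
    the fitted density are long since fixed.

    eta_of(alpha) -> flat linear predictor; system_of(w, z) -> (M, rhs)
    for the weighted penalized normal equations; pen_value(alpha) -> the
    penalty term of the objective.
    """
    eta = eta_of(alpha)
    mu = _safe_mu(eta)
    pll = float(np.sum(yv * eta - mu)) - pen_value(alpha)
    iterations = 0
    converged = False
    for iterations in range(1, maxit + 1):
        w = np.maximum(mu, MU_FLOOR)
        z = eta + (yv - w) / w
        m, rhs = system_of(w, z)
        step = np.linalg.solve(m, rhs) - alpha
        t = 1.0
        for _ in range(40):
            cand = alpha + t * step
            eta_c = eta_of(cand)
            mu_c = _safe_mu(eta_c)
            pll_c = float(np.sum(yv * eta_c - mu_c)) - pen_value(cand)
            if pll_c >= pll - 1e-12 * max(1.0, abs(pll)):
                break
            t /= 2.0
        delta = float(np.max(np.abs(cand - alpha)))
        obj_change = abs(pll_c - pll)
        alpha, eta, mu, pll = cand, eta_c, mu_c, pll_c
        if delta < tol or obj_change < 1e-11 * max(1.0, abs(pll)):
            converged = True
            break
    return alpha, iterations, converged, pll


def fit_pspline_poisson_1d(
    y,
    basis: BSplineBasis,
    pen: PenaltyConfig = PenaltyConfig(),
    tol: float = 1e-6,
    maxit: int = 50,
) -> SmoothFit1D:
    """Fit a smooth log-density to 1-D histogram counts.

    Maximizes sum(y * eta - mu) - (lam/2) * ||D alpha||^2 with
    eta = B alpha, mu = exp(eta), by IRLS: repeatedly solve

        (B' W B + lam D'D) alpha = B' W z,   W = diag(mu~),
        z = eta~ + (y - mu~) / mu~

    until the maximum absolute coefficient change drops below ``tol``.
    Non-convergence within ``maxit`` is flagged, not fatal.
    """
    y = np.asarray(y, float)
    if y.ndim != 1 or len(y) != basis.matrix.shape[0]:
        raise ConfigError("y length must match the basis eval points")
    if np.any(y < 0):
        raise InputError("counts must be non-negative")
    if not np.any(y > 0):
        raise InputError("all-zero counts: nothing to fit")

    b = basis.matrix
    n = basis.n_bases
    d = difference_matrix(n, pen.order)
    p = pen.lam * (d.T @ d) + RIDGE * np.eye(n)

    alpha0 = _init_alpha(b.T @ b, b.T @ np.log1p(y), p, n)

    def system_of(w, z):
        bw = b * w[:, None]
        return bw.T @ b + p, bw.T @ z

    alpha, iterations, converged, pll = _irls(
        y, alpha0,
        eta_of=lambda a: b @ a,
        system_of=system_of,
        pen_value=lambda a: _penalty_value_1d(a, d, pen.lam),
        tol=tol, maxit=maxit,
    )
    eta = b @ alpha
    return SmoothFit1D(
        alpha=alpha, eta=eta, mu=np.exp(eta),
        iterations=iterations, converged=converged, penalized_loglik=pll,
    )


def _glam_inner(br: np.ndarray, bc: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted inner-product matrix of the tensor-product design without
    forming the Kronecker product.

    Row-major vectorization: coefficient (k, l) maps to index k * n_c + l,
    so the full design is kron(Br, Bc).  Entry ((k,l), (m,n)) equals
    sum_ij W_ij Br_ik Br_im Bc_jl Bc_jn.
    """
    a1 = np.einsum("ik,im,ij->kmj", br, br, w, optimize=True)
    a = np.einsum("kmj,jl,jn->kmln", a1, bc, bc, optimize=True)
    nr, nc = br.shape[1], bc.shape[1]
    return a.transpose(0, 2, 1, 3).reshape(nr * nc, nr * nc)


def _penalty_2d(nr: int, nc: int, pen: PenaltyConfig):
    """Penalty matrix for row-major vec(C): third differences down the
    columns of C (row index) and along the rows of C (column index)."""
    dr = difference_matrix(nr, pen.order)
    dc = difference_matrix(nc, pen.order)
    p = pen.lam_r * np.kron(dr.T @ dr, np.eye(nc))
    p += pen.lam_col * np.kron(np.eye(nr), dc.T @ dc)
    return p, dr, dc


def _penalty_value_2d(coef, dr, dc, pen: PenaltyConfig) -> float:
    return 0.5 * (
        pen.lam_r * float(np.sum((dr @ coef) ** 2))
        + pen.lam_col * float(np.sum((coef @ dc.T) ** 2))
    )


def _check_2d_inputs(y, basis_r, basis_c):
    y = np.asarray(y, float)
    if y.shape != (basis_r.matrix.shape[0], basis_c.matrix.shape[0]):
        raise ConfigError(
            f"count matrix shape {y.shape} does not match bases "
            f"({basis_r.matrix.shape[0]}, {basis_c.matrix.shape[0]})"
        )
    if np.any(y < 0):
        raise InputError("counts must be non-negative")
    if not np.any(y > 0):
        raise InputError("all-zero counts: nothing to fit")
    return y


def fit_pspline_poisson_2d(
    y,
    basis_r: BSplineBasis,
    basis_c: BSplineBasis,
    pen: PenaltyConfig = PenaltyConfig(),
    tol: float = 1e-6,
    maxit: int = 50,
    init_coef: np.ndarray | None = None,
) -> SmoothFit2D:
    """Fit a smooth 2-D log-density to a histogram count matrix.

    The linear predictor is Eta = Br C Bc', with squared third-difference
    penalties on both the rows and the columns of the coefficient matrix C
    (Frobenius norms, one lambda per direction).  The IRLS normal
    equations are assembled with GLAM-style einsum contractions, so cost
    scales with the grid and basis sizes only, never with n_SNPs, and the
    Kronecker design is never materialized.

    ``init_coef`` warm-starts IRLS (used by the EM layer between
    iterations).
    """
    y = _check_2d_inputs(y, basis_r, basis_c)
    br, bc = basis_r.matrix, basis_c.matrix
    nr, nc = basis_r.n_bases, basis_c.n_bases
    p, dr, dc = _penalty_2d(nr, nc, pen)
    p = p + RIDGE * np.eye(nr * nc)

    nx, ny = y.shape
    if init_coef is not None:
        alpha0 = np.asarray(init_coef, float).ravel().copy()
    else:
        ones = np.ones_like(y)
        rhs = (br.T @ np.log1p(y) @ bc).ravel()
        alpha0 = _init_alpha(_glam_inner(br, bc, ones), rhs, p, nr * nc)

    def system_of(w, z):
        wm = w.reshape(nx, ny)
        m = _glam_inner(br, bc, wm) + p
        rhs = (br.T @ (wm * z.reshape(nx, ny)) @ bc).ravel()
        return m, rhs

    alpha, iterations, converged, pll = _irls(
        y.ravel(), alpha0,
        eta_of=lambda a: (br @ a.reshape(nr, nc) @ bc.T).ravel(),
        system_of=system_of,
        pen_value=lambda a: _penalty_value_2d(a.reshape(nr, nc), dr, dc, pen),
        tol=tol, maxit=maxit,
    )
    coef = alpha.reshape(nr, nc)
    eta = br @ coef @ bc.T
    return SmoothFit2D(
        coef=coef, eta=eta, mu=np.exp(eta),
        iterations=iterations, converged=converged, penalized_loglik=pll,
    )


def naive_fit_2d_kron(
    y,
    basis_r: BSplineBasis,
    basis_c: BSplineBasis,
    pen: PenaltyConfig = PenaltyConfig(),
    tol: float = 1e-6,
    maxit: int = 50,
    init_coef: np.ndarray | None = None,
) -> SmoothFit2D:
    """Explicit-Kronecker formulation of the 2-D fit (cross-check only).

    Vectorizes the count matrix and builds the full kron(Br, Bc) design,
    then runs the same IRLS recursion.  Deliberately inefficient; refuses
    problems with more than NAIVE_SIZE_LIMIT total basis functions.
    """
    y = _check_2d_inputs(y, basis_r, basis_c)
    br, bc = basis_r.matrix, basis_c.matrix
    nr, nc = basis_r.n_bases, basis_c.n_bases
    if nr * nc > NAIVE_SIZE_LIMIT:
        raise ConfigError(
            f"naive Kronecker path limited to {NAIVE_SIZE_LIMIT} basis "
            f"functions, got {nr * nc}"
        )
    x = np.kron(br, bc)  # row-major vec: (i, j) -> i * ny + j
    yv = y.ravel()
    p, dr, dc = _penalty_2d(nr, nc, pen)
    p = p + RIDGE * np.eye(nr * nc)

    if init_coef is not None:
        alpha0 = np.asarray(init_coef, float).ravel().copy()
    else:
        alpha0 = _init_alpha(x.T @ x, x.T @ np.log1p(yv), p, nr * nc)

    def system_of(w, z):
        xw = x * w[:, None]
        return xw.T @ x + p, xw.T @ z

    alpha, iterations, converged, pll = _irls(
        yv, alpha0,
        eta_of=lambda a: x @ a,
        system_of=system_of,
        pen_value=lambda a: _penalty_value_2d(a.reshape(nr, nc), dr, dc, pen),
        tol=tol, maxit=maxit,
    )
    coef = alpha.reshape(nr, nc)
    eta = (x @ alpha).reshape(y.shape)
    return SmoothFit2D(
        coef=coef, eta=eta, mu=np.exp(eta),
        iterations=iterations, converged=converged, penalized_loglik=pll,
    )
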
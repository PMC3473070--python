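"""EM estimation of the three-genotype mixture of smooth log-concave
densities on the 2-D histogram.

The mixture has no explicit mixing-proportion parameters: each component
is an unnormalized smooth intensity surface, and the proportions are
implicit in the pseudo-count totals.  Two steps alternate until the
per-bin membership probabilities stop changing:

* E-step: split each bin's observed count into three fractional
  pseudo-counts proportional to the current component intensities
  (pseudo-counts always sum to the observed histogram, exactly);
* M-step: refit each component's penalized Poisson P-spline surface on
  its pseudo-counts.

The maximum of the three normalized memberships in a bin (P*) measures
calling confidence; with three components its floor is 1/3, attained
only when all three intensities tie.

The algorithm is deterministic: no randomness anywhere in the fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, RangeError
from .gridding import GridSpec, Histogram2D
from .psplines import (
    BSplineBasis,
    PenaltyConfig,
    SmoothFit2D,
    _penalty_value_2d,
    bspline_basis,
    difference_matrix,
    fit_pspline_poisson_2d,
)
from .signals import GENOTYPES

#: a component whose pseudo-count total drops below this is declared extinct
EXTINCTION_TOTAL = 1.0

#: total mass (as a fraction of n) of the flat density a frozen component keeps
FROZEN_MASS_FRACTION = 1e-6


@dataclass
class PseudoCounts:
    """Three fractional count matrices, one per genotype component.

    Invariant: comps.sum(axis=0) equals the observed histogram exactly.
    """

    comps: np.ndarray  # (3, nx, ny), order (AA, AB, BB)

    def totals(self) -> np.ndarray:
        return self.comps.sum(axis=(1, 2))


@dataclass
class MixtureFit:
    """A fitted three-component mixture on one array's histogram."""

    components: list  # three SmoothFit2D (None where frozen)
    mu: np.ndarray  # (3, nx, ny) expected counts per component
    membership: np.ndarray  # (3, nx, ny), per bin sums to 1
    pstar: np.ndarray  # (nx, ny) per-bin maximum membership
    grid: GridSpec
    em_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    frozen: np.ndarray = field(default=None)  # (3,) bool, extinct components
    pen: PenaltyConfig = None
    bases: tuple = None  # (basis_r, basis_c)


def initialize_pseudocounts(
    hist: Histogram2D, split_lo: float = -0.2, split_hi: float = 0.2
) -> PseudoCounts:
    """Hard three-sector split of the histogram by bin-midpoint contrast.

    Each bin's full count goes to the single component of its sector:
    contrast midpoint < split_lo -> AA, <= split_hi -> AB, else BB.  A
    sector with zero total count triggers a warning; the EM layer then
    freezes that component at a flat floor density.
    """
    if not split_lo < split_hi:
        raise ConfigError("split_lo must be < split_hi")
    y_mid = hist.grid.y_mid
    comps = np.zeros((3,) + hist.counts.shape, float)
    sector = np.where(y_mid < split_lo, 0, np.where(y_mid > split_hi, 2, 1))
    for k in range(3):
        comps[k][:, sector == k] = hist.counts[:, sector == k]
    pc = PseudoCounts(comps=comps)
    empty = pc.totals() == 0
    if empty.any():
        names = [GENOTYPES[k] for k in np.flatnonzero(empty)]
        warnings.warn(
            f"seed sector(s) {names} contain no counts; the corresponding "
            "component(s) will be frozen at a flat floor density",
            stacklevel=2,
        )
    return pc


def default_bases(
    grid: GridSpec, nseg: int = 10, degree: int = 3
) -> tuple[BSplineBasis, BSplineBasis]:
    """Bases on the grid midpoints: nseg + degree functions per direction
    (default 10 + 3 cubic B-splines over each histogram axis)."""
    br = bspline_basis(grid.x_mid, grid.x_edges[0], grid.x_edges[-1], nseg, degree)
    bc = bspline_basis(grid.y_mid, grid.y_edges[0], grid.y_edges[-1], nseg, degree)
    return br, bc


def em_fit(
    hist: Histogram2D,
    basis_r: BSplineBasis | None = None,
    basis_c: BSplineBasis | None = None,
    pen: PenaltyConfig = PenaltyConfig(),
    init: PseudoCounts | None = None,
    split_lo: float = -0.2,
    split_hi: float = 0.2,
    em_tol: float = 1e-4,
    em_maxit: int = 50,
    irls_tol: float = 1e-8,
    irls_maxit: int = 50,
) -> MixtureFit:
    """Fit the three-component mixture by EM on the histogram.

    Convergence is declared when the maximum absolute change of any
    per-bin membership probability, over bins that contain data, falls
    below ``em_tol`` — directly interpretable and tied to the genotype
    calls (memberships of empty bins can never move a call), unlike a raw
    log-likelihood change.  The penalized log-likelihood trace is stored
    and is non-decreasing (up to M-step solver tolerance).

    A component whose pseudo-count total falls below 1 (possible at
    extreme MAF) is frozen at a flat density of total mass 1e-6 * n and
    stays frozen; EM continues with the remaining components.
    """
    if basis_r is None or basis_c is None:
        br_def, bc_def = default_bases(hist.grid)
        basis_r = basis_r or br_def
        basis_c = basis_c or bc_def
    counts = hist.counts.astype(float)
    n = counts.sum()
    if init is None:
        init = initialize_pseudocounts(hist, split_lo, split_hi)
    pseudo = init.comps.copy()

    nx, ny = counts.shape
    flat_mu = np.full((nx, ny), FROZEN_MASS_FRACTION * n / (nx * ny))
    frozen = np.zeros(3, bool)
    fits: list[SmoothFit2D | None] = [None, None, None]
    mu = np.zeros((3, nx, ny))
    membership_prev = None
    trace = []
    converged = False
    em_iterations = 0

    for em_iterations in range(1, em_maxit + 1):
        # M-step: smooth each component's pseudo-counts
        for k in range(3):
            if frozen[k] or pseudo[k].sum() < EXTINCTION_TOTAL:
                if not frozen[k]:
                    warnings.warn(
                        f"component {GENOTYPES[k]} extinct "
                        f"(pseudo-count total {pseudo[k].sum():.3g}); "
                        "frozen at a flat floor density",
                        stacklevel=2,
                    )
                frozen[k] = True
                fits[k] = None
                mu[k] = flat_mu
            else:
                warm = fits[k].coef if fits[k] is not None else None
                fits[k] = fit_pspline_poisson_2d(
                    pseudo[k], basis_r, basis_c, pen,
                    tol=irls_tol, maxit=irls_maxit, init_coef=warm,
                )
                mu[k] = fits[k].mu

        # E-step: normalized memberships and new pseudo-counts
        mu_tot = np.maximum(mu.sum(axis=0), 1e-300)
        membership = mu / mu_tot
        pseudo = counts * membership

        dr = difference_matrix(basis_r.n_bases, pen.order)
        dc = difference_matrix(basis_c.n_bases, pen.order)
        pll = float(np.sum(counts * np.log(mu_tot)) - mu_tot.sum())
        for k in range(3):
            if fits[k] is not None:
                pll -= _penalty_value_2d(fits[k].coef, dr, dc, pen)
        trace.append(pll)

        if membership_prev is not None:
            # convergence is judged on occupied bins only: every SNP sits in
            # a bin with count >= 1, so this is the change that can move calls
            occ = counts > 0
            delta = float(
                np.max(np.abs(membership[:, occ] - membership_prev[:, occ]))
            )
            if delta < em_tol:
                membership_prev = membership
                converged = True
                break
        membership_prev = membership

    pstar = membership_prev.max(axis=0)
    return MixtureFit(
        components=fits, mu=mu.copy(), membership=membership_prev, pstar=pstar,
        grid=hist.grid, em_iterations=em_iterations, converged=converged,
        loglik_trace=np.asarray(trace), frozen=frozen, pen=pen,
        bases=(basis_r, basis_c),
    )


def membership_at(fit: MixtureFit, bin_index) -> tuple[np.ndarray, float]:
    """Membership probability triple (AA, AB, BB) and P* for one bin."""
    i, j = int(bin_index[0]), int(bin_index[1])
    nx, ny = fit.pstar.shape
    if not (0 <= i < nx and 0 <= j < ny):
        raise RangeError(f"bin index ({i}, {j}) outside grid {nx} x {ny}")
    triple = fit.membership[:, i, j]
    return triple, float(triple.max())


def save_mixture(fit: MixtureFit, path) -> None:
    """Serialize a fitted mixture (grid, bases, coefficients, lambda) to
    JSON for reuse and inspection."""
    basis_r, basis_c = fit.bases
    payload = {
        "grid": {
            "x_edges": fit.grid.x_edges.tolist(),
            "y_edges": fit.grid.y_edges.tolist(),
        },
        "basis": {"nseg_r": basis_r.nseg, "nseg_c": basis_c.nseg,
                  "degree": basis_r.degree},
        "penalty": {"order": fit.pen.order, "lam": fit.pen.lam_r,
                    "lam_c": fit.pen.lam_col},
        "components": [
            None if f is None else f.coef.tolist() for f in fit.components
        ],
        "frozen": fit.frozen.tolist(),
        "em_iterations": fit.em_iterations,
        "converged": fit.converged,
        "loglik_trace": fit.loglik_trace.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_mixture(path) -> MixtureFit:
    """Rebuild a MixtureFit from a JSON sidecar written by save_mixture."""
    with open(path) as fh:
        payload = json.load(fh)
    grid = GridSpec(
        x_edges=np.asarray(payload["grid"]["x_edges"]),
        y_edges=np.asarray(payload["grid"]["y_edges"]),
    )
    b = payload["basis"]
    basis_r = bspline_basis(grid.x_mid, grid.x_edges[0], grid.x_edges[-1],
                            b["nseg_r"], b["degree"])
    basis_c = bspline_basis(grid.y_mid, grid.y_edges[0], grid.y_edges[-1],
                            b["nseg_c"], b["degree"])
    pen = PenaltyConfig(order=payload["penalty"]["order"],
                        lam=payload["penalty"]["lam"],
                        lam_c=payload["penalty"]["lam_c"])
    n_flat = 1.0  # frozen components are reconstructed at unit mass
    mu = np.zeros((3, grid.nx, grid.ny))
    fits = []
    for k, coef in enumerate(payload["components"]):
        if coef is None:
            fits.append(None)
            mu[k] = n_flat / (grid.nx * grid.ny)
        else:
            c = np.asarray(coef)
            eta = basis_r.matrix @ c @ basis_c.matrix.T
            fits.append(SmoothFit2D(coef=c, eta=eta, mu=np.exp(eta),
                                    iterations=0, converged=True,
                                    penalized_loglik=float("nan")))
            mu[k] = fits[-1].mu
    mu_tot = np.maximum(mu.sum(axis=0), 1e-300)
    membership = mu / mu_tot
    return MixtureFit(
        components=fits, mu=mu, membership=membership,
        pstar=membership.max(axis=0), grid=grid,
        em_iterations=payload["em_iterations"], converged=payload["converged"],
        loglik_trace=np.asarray(payload["loglik_trace"]),
        frozen=np.asarray(payload["frozen"], bool), pen=pen,
        bases=(basis_r, basis_c),
    )
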
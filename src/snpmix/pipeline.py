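"""End-to-end pipeline: raw signals -> transform -> histogram -> EM fit ->
per-SNP genotype calls.  Deterministic: identical inputs and configuration
give identical output, byte for byte."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import pandas as pd

from .calling import apply_nocall_threshold, call_genotypes
from .config import RunConfig
from .gridding import GridSpec, Histogram2D, build_histogram, make_grid
from .mixture import MixtureFit, default_bases, em_fit
from .psplines import PenaltyConfig
from .signals import transform_signals

logger = logging.getLogger("snpmix")


@dataclass
class CallResult:
    calls: pd.DataFrame
    fit: MixtureFit
    grid: GridSpec
    hist: Histogram2D
    transformed: pd.DataFrame
    timings: dict


def call_array(signals: pd.DataFrame, config: RunConfig | None = None) -> CallResult:
    """Genotype all SNPs of one array at once.

    The mixture is fitted on the 2-D histogram, so the cost of the fit is
    almost independent of the number of SNPs; only the transform and the
    binning scale with n.
    """
    cfg = config or RunConfig()
    timings = {}

    t0 = time.perf_counter()
    transformed = transform_signals(signals, clip_floor=cfg.clip_floor)
    timings["transform"] = time.perf_counter() - t0
    n_clipped = int(transformed["clipped"].sum())
    if n_clipped:
        logger.warning("%d SNP(s) had intensities clipped to the floor", n_clipped)

    t0 = time.perf_counter()
    grid = make_grid(
        transformed, nx=cfg.nx, ny=cfg.ny, pad_fraction=cfg.pad_fraction,
        x_limits=cfg.x_limits, y_limits=cfg.y_limits,
    )
    hist = build_histogram(transformed, grid)
    timings["histogram"] = time.perf_counter() - t0
    n_clamped = int(hist.clamped.sum())
    if n_clamped:
        logger.warning("%d SNP(s) clamped to boundary bins", n_clamped)

    t0 = time.perf_counter()
    basis_r, basis_c = default_bases(grid, nseg=cfg.nseg, degree=cfg.degree)
    pen = PenaltyConfig(order=cfg.penalty_order, lam=cfg.lam, lam_c=cfg.lam_c)
    fit = em_fit(
        hist, basis_r, basis_c, pen,
        split_lo=cfg.split_lo, split_hi=cfg.split_hi,
        em_tol=cfg.em_tol, em_maxit=cfg.em_maxit,
        irls_tol=cfg.irls_tol, irls_maxit=cfg.irls_maxit,
    )
    timings["em_fit"] = time.perf_counter() - t0
    logger.info(
        "EM finished after %d iterations (converged=%s)",
        fit.em_iterations, fit.converged,
    )
    if fit.frozen.any():
        logger.warning("frozen (extinct) components: %s", fit.frozen.tolist())

    t0 = time.perf_counter()
    calls = call_genotypes(transformed, fit, grid)
    calls = apply_nocall_threshold(calls, cfg.nocall_threshold)
    timings["calling"] = time.perf_counter() - t0

    return CallResult(
        calls=calls, fit=fit, grid=grid, hist=hist,
        transformed=transformed, timings=timings,
    )
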
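"""Synthetic single-array intensity data with known genotypes.

Emulates the cluster geometry of real genotyping arrays in the
(strength, contrast) plane: three compact clusters, AA below, AB around
zero contrast, BB above.  Per SNP a minor-allele frequency p is drawn,
the genotype follows Hardy-Weinberg proportions ((1-p)^2, 2p(1-p), p^2),
a point is sampled from the genotype's Gaussian cluster, and the
transform is inverted to produce linear-scale two-channel signals.

Two platform presets capture the qualitative difference between array
chemistries: a one-color design gives clusters symmetric about zero
contrast with overlapping tails, while a two-dye design gives tighter,
asymmetric clusters with near-zero density between them (hence higher
calling confidence).  A low-MAF stress preset exercises arrays where one
or two genotype clusters are nearly or entirely absent.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .signals import GENOTYPES

PLATFORM_PRESETS = ("affymetrix_like", "illumina_like")


@dataclass
class SimConfig:
    """Generative model for one synthetic array.

    cluster_centers are (strength, contrast) pairs in the order
    (AA, AB, BB); cluster_spreads are 2x2 covariance matrices in the same
    order.  ``skew`` bends each cluster: strength is shifted by
    skew * (contrast - center_contrast)^2, a quadratic shear that mimics
    two-dye asymmetry.  maf_dist is one of "fixed" (params: value),
    "uniform" (lo, hi), "beta" (a, b; scaled to [0, 0.5]) or "choice"
    (a discrete set of MAF values, equal probability).
    """

    n_snps: int = 10_000
    maf_dist: str = "uniform"
    maf_params: tuple = (0.05, 0.5)
    cluster_centers: tuple = (
        (2.0, -1.2),
        (2.15, 0.0),
        (2.0, 1.2),
    )
    cluster_spreads: tuple = (
        ((0.25**2, 0.0), (0.0, 0.18**2)),
        ((0.25**2, 0.0), (0.0, 0.18**2)),
        ((0.25**2, 0.0), (0.0, 0.18**2)),
    )
    skew: tuple = (0.0, 0.0, 0.0)
    platform_preset: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ConfigError(f"n_snps must be >= 1, got {self.n_snps}")
        for k, cov in enumerate(self.cluster_spreads):
            c = np.asarray(cov, float)
            if c.shape != (2, 2) or np.any(np.linalg.eigvalsh(c) <= 0):
                raise ConfigError(
                    f"cluster_spreads[{k}] must be a 2x2 positive-definite matrix"
                )


def preset(platform: str, n_snps: int = 10_000, seed: int = 0) -> SimConfig:
    """Named platform configurations.

    affymetrix_like: clusters symmetric about contrast 0 at (-1.2, 0, 1.2),
    contrast spread 0.18 (separation/spread ~ 6.7), overlapping tails.
    illumina_like: tighter (spread 0.10-0.12), asymmetric centers and a
    quadratic bend, leaving near-zero density between clusters.
    """
    if platform == "affymetrix_like":
        return SimConfig(n_snps=n_snps, seed=seed, platform_preset=platform)
    if platform == "illumina_like":
        sp = lambda s_s, s_c: ((s_s**2, 0.0), (0.0, s_c**2))
        return SimConfig(
            n_snps=n_snps,
            seed=seed,
            platform_preset=platform,
            cluster_centers=((2.3, -1.8), (2.55, 0.25), (2.3, 2.1)),
            cluster_spreads=(sp(0.12, 0.10), sp(0.12, 0.12), sp(0.12, 0.10)),
            skew=(-0.10, -0.10, -0.10),
        )
    raise ConfigError(
        f"unknown platform {platform!r}; valid presets: {PLATFORM_PRESETS}"
    )


def low_maf_stress(n_snps: int = 10_000, seed: int = 0) -> SimConfig:
    """Stress configuration: per-SNP MAF drawn from {0, 0.01, 0.05}, so the
    heterozygous cluster is sparse and the minor homozygote nearly (or
    entirely) empty — exercising extinct-component handling and calling
    quality in the low-MAF regime."""
    return SimConfig(
        n_snps=n_snps,
        seed=seed,
        maf_dist="choice",
        maf_params=(0.0, 0.01, 0.05),
    )


def _draw_maf(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.maf_dist == "fixed":
        p = np.full(cfg.n_snps, float(cfg.maf_params[0]))
    elif cfg.maf_dist == "uniform":
        lo, hi = cfg.maf_params
        p = rng.uniform(lo, hi, cfg.n_snps)
    elif cfg.maf_dist == "beta":
        a, b = cfg.maf_params
        p = 0.5 * rng.beta(a, b, cfg.n_snps)
    elif cfg.maf_dist == "choice":
        p = rng.choice(np.asarray(cfg.maf_params, float), size=cfg.n_snps)
    else:
        raise ConfigError(f"unknown maf_dist {cfg.maf_dist!r}")
    if np.any(p < 0) or np.any(p > 0.5):
        raise ConfigError("MAF values must lie in [0, 0.5]")
    return p


def simulate_array(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one array: (RawSignalTable, truth table).

    Returns (signals, truth) where signals has columns snp_id, signal_A,
    signal_B (linear scale) and truth has snp_id, genotype, maf.
    Deterministic given cfg.seed; transform_signals() recovers the
    sampled (strength, contrast) points exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    p = _draw_maf(cfg, rng)  # frequency of the B allele's minor variant
    # Hardy-Weinberg genotype probabilities with B-allele frequency p
    probs = np.column_stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    u = rng.random(cfg.n_snps)
    geno = (u[:, None] >= probs.cumsum(axis=1)).sum(axis=1)

    strength = np.empty(cfg.n_snps)
    contrast = np.empty(cfg.n_snps)
    for k in range(3):
        mask = geno == k
        m = int(mask.sum())
        if m == 0:
            continue
        center = np.asarray(cfg.cluster_centers[k], float)
        cov = np.asarray(cfg.cluster_spreads[k], float)
        pts = rng.multivariate_normal(center, cov, size=m, method="cholesky")
        s, c = pts[:, 0], pts[:, 1]
        s = s + cfg.skew[k] * (c - center[1]) ** 2
        strength[mask] = s
        contrast[mask] = c

    # invert the transform: log10 A = strength - contrast/2, etc.
    signal_a = 10.0 ** (strength - contrast / 2.0)
    signal_b = 10.0 ** (strength + contrast / 2.0)
    ids = np.array([f"snp{i:07d}" for i in range(cfg.n_snps)])
    signals = pd.DataFrame(
        {"snp_id": ids, "signal_A": signal_a, "signal_B": signal_b}
    )
    truth = pd.DataFrame(
        {"snp_id": ids,
         "genotype": np.array(GENOTYPES, dtype=object)[geno],
         "maf": p}
    )
    return signals, truth


def write_sim_sidecar(cfg: SimConfig, path) -> None:
    """Record the full generative configuration (including the seed)."""
    with open(path, "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)
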
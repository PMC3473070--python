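"""Two-dimensional histogram of all SNPs on one array.

Binning the (strength, contrast) cloud once makes the cost of the density
fit independent of the number of SNPs: the mixture is estimated from the
count matrix, and each SNP later inherits the membership probabilities of
its bin.

Bins are half-open [lo, hi) except the last bin in each direction, which
is closed on the right, so the domain maximum is never lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, RangeError


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectangular grid on the (strength, contrast) plane.

    x is strength, y is contrast.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self):
        for name, e in (("x_edges", self.x_edges), ("y_edges", self.y_edges)):
            e = np.asarray(e, float)
            if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
                raise ConfigError(f"{name} must be strictly increasing, length >= 2")
            object.__setattr__(self, name, e)

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def x_mid(self) -> np.ndarray:
        return (self.x_edges[:-1] + self.x_edges[1:]) / 2.0

    @property
    def y_mid(self) -> np.ndarray:
        return (self.y_edges[:-1] + self.y_edges[1:]) / 2.0


@dataclass
class Histogram2D:
    """Count matrix plus the bin membership of every SNP.

    ``counts[i, j]`` is the number of SNPs with strength in x-bin i and
    contrast in y-bin j; sum(counts) equals the number of SNPs.
    """

    counts: np.ndarray  # (nx, ny) non-negative integers
    grid: GridSpec
    bin_index: np.ndarray  # (n, 2) int pairs (i, j)
    clamped: np.ndarray = field(default=None)  # (n,) bool, outside-domain flags

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())


def make_grid(
    transformed: pd.DataFrame,
    nx: int = 100,
    ny: int = 100,
    pad_fraction: float = 0.01,
    x_limits: tuple | None = None,
    y_limits: tuple | None = None,
) -> GridSpec:
    """Build a uniform nx-by-ny grid covering the data (default 100 x 100).

    The domain is the data range padded by ``pad_fraction`` of the range
    on each side, unless explicit limits are given.  Padding keeps the
    extreme bins away from B-spline boundary effects.
    """
    if nx < 8 or ny < 8:
        raise ConfigError(f"nx and ny must be >= 8, got {nx} x {ny}")
    if pad_fraction < 0:
        raise ConfigError("pad_fraction must be >= 0")

    def _limits(values, explicit, name):
        if explicit is not None:
            lo, hi = float(explicit[0]), float(explicit[1])
        else:
            lo, hi = float(np.min(values)), float(np.max(values))
            rng = hi - lo
            if rng == 0:
                raise ConfigError(
                    f"degenerate {name} range (all values {lo}); "
                    "pass explicit limits"
                )
            lo -= pad_fraction * rng
            hi += pad_fraction * rng
        if not lo < hi:
            raise ConfigError(f"invalid {name} limits ({lo}, {hi})")
        return lo, hi

    x_lo, x_hi = _limits(transformed["strength"].to_numpy(float), x_limits, "strength")
    y_lo, y_hi = _limits(transformed["contrast"].to_numpy(float), y_limits, "contrast")
    return GridSpec(
        x_edges=np.linspace(x_lo, x_hi, nx + 1),
        y_edges=np.linspace(y_lo, y_hi, ny + 1),
    )


def _bin_1d(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Half-open bins [e_i, e_{i+1}); the final bin is closed on the right.

    Returns (indices, outside) where outside flags values beyond the domain;
    those indices are clamped to the boundary bins.
    """
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2  # closed last bin
    outside = (idx < 0) | (idx > len(edges) - 2)
    return np.clip(idx, 0, len(edges) - 2), outside


def assign_bins(
    transformed: pd.DataFrame, grid: GridSpec, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Map each SNP to its (i, j) bin; returns (bin_index, clamped flags)."""
    ix, out_x = _bin_1d(transformed["strength"].to_numpy(float), grid.x_edges)
    iy, out_y = _bin_1d(transformed["contrast"].to_numpy(float), grid.y_edges)
    outside = out_x | out_y
    if outside.any() and not clamp:
        ids = transformed.loc[outside, "snp_id"].tolist()
        raise RangeError(
            f"{outside.sum()} SNP(s) outside the grid, e.g. {ids[:5]}; "
            "enable clamping or widen the grid"
        )
    return np.column_stack([ix, iy]), outside


def build_histogram(
    transformed: pd.DataFrame, grid: GridSpec, clamp: bool = True
) -> Histogram2D:
    """Count SNPs per bin and record every SNP's bin index.

    Total count is preserved: points outside an explicitly supplied domain
    are clamped to the nearest boundary bin and flagged rather than dropped.
    """
    bin_index, clamped = assign_bins(transformed, grid, clamp=clamp)
    counts = np.zeros((grid.nx, grid.ny), dtype=np.int64)
    np.add.at(counts, (bin_index[:, 0], bin_index[:, 1]), 1)
    return Histogram2D(counts=counts, grid=grid, bin_index=bin_index, clamped=clamped)
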
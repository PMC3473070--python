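"""Genotype calls from a fitted mixture, plus evaluation machinery:
concordance cross-tables, minor allele frequency, and quality summaries.

Every SNP inherits the membership probability triple of its histogram bin;
the largest probability determines the call.  All three probabilities are
stored per SNP, so a NoCall threshold can be applied (or changed) later
without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError, SnpmixError
from .gridding import GridSpec, assign_bins
from .mixture import MixtureFit
from .signals import CALL_LABELS, GENOTYPES

PROB_COLUMNS = ("p_AA", "p_AB", "p_BB")


@dataclass
class ConcordanceTable:
    """4x4 cross-table of calls: rows = this method, columns = reference."""

    counts: pd.DataFrame  # labels (AA, AB, BB, NN) on both axes
    n_compared: int
    n_only_calls: int  # SNPs present only in the call table
    n_only_reference: int

    def percent(self) -> pd.DataFrame:
        """Column-normalized view: each non-empty column sums to 100."""
        totals = self.counts.sum(axis=0)
        pct = self.counts.astype(float)
        nonzero = totals > 0
        pct.loc[:, nonzero] = 100.0 * pct.loc[:, nonzero] / totals[nonzero]
        pct.loc[:, ~nonzero] = 0.0
        return pct


def call_genotypes(
    transformed: pd.DataFrame, fit: MixtureFit, grid: GridSpec | None = None
) -> pd.DataFrame:
    """Assign every SNP the genotype with the largest membership probability.

    Each SNP is mapped to its histogram bin and receives that bin's
    normalized probability triple; the call is the argmax.  Exact ties
    (measure zero) break deterministically toward AB, then AA, and are
    flagged.  No NN is produced here; apply a threshold afterwards if
    desired.
    """
    grid = grid if grid is not None else fit.grid
    if grid.nx != fit.pstar.shape[0] or grid.ny != fit.pstar.shape[1]:
        raise SnpmixError("grid does not match the fitted mixture (shape mismatch)")
    bin_index, clamped = assign_bins(transformed, grid, clamp=True)
    p_aa, p_ab, p_bb = fit.membership[:, bin_index[:, 0], bin_index[:, 1]]

    # argmax with the documented tie preference AB > AA > BB
    is_ab = (p_ab >= p_aa) & (p_ab >= p_bb)
    is_aa = ~is_ab & (p_aa >= p_bb)
    call_idx = np.where(is_ab, 1, np.where(is_aa, 0, 2)).astype(np.int8)
    pstar = np.maximum(np.maximum(p_aa, p_ab), p_bb)
    tie = (
        (p_aa == pstar).astype(np.int8)
        + (p_ab == pstar)
        + (p_bb == pstar)
    ) > 1

    call = pd.Categorical.from_codes(call_idx, categories=list(CALL_LABELS))
    out = pd.DataFrame(
        {
            "snp_id": transformed["snp_id"].to_numpy(),
            "call": call,
            "p_AA": p_aa,
            "p_AB": p_ab,
            "p_BB": p_bb,
            "pstar": pstar,
            "clipped": (
                transformed["clipped"].to_numpy()
                if "clipped" in transformed
                else np.zeros(len(transformed), bool)
            ),
            "clamped": clamped,
            "tie": tie,
        },
        copy=False,
    )
    return out


def apply_nocall_threshold(calls: pd.DataFrame, threshold: float | None) -> pd.DataFrame:
    """Set call = NN where P* falls below the threshold.

    The threshold must lie in [1/3, 1] (below 1/3 it can never fire,
    since P* >= 1/3 by construction).  Probabilities are retained, so the
    operation is idempotent and reversible.  ``threshold=None`` is the
    identity (the default policy is to accept every classification).
    """
    if threshold is None:
        # identity: new frame, shared (immutable-by-contract) columns —
        # a deep copy of a million-row id column would dominate runtime
        return calls.copy(deep=False)
    if not (1.0 / 3.0 <= threshold <= 1.0):
        raise ConfigError(f"nocall threshold must be in [1/3, 1], got {threshold}")
    out = calls.copy()
    out.loc[out["pstar"] < threshold, "call"] = "NN"
    return out


def read_calls(path) -> pd.DataFrame:
    """Read a call table TSV (at minimum snp_id, call).

    A ``genotype`` column (as written by the simulator's truth table) is
    accepted as an alias for ``call``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    if "call" not in df.columns and "genotype" in df.columns:
        df = df.rename(columns={"genotype": "call"})
    missing = {"snp_id", "call"} - set(df.columns)
    if missing:
        raise InputError(f"call table missing columns: {sorted(missing)}")
    bad = ~df["call"].isin(CALL_LABELS)
    if bad.any():
        raise InputError(
            f"unknown call labels: {sorted(df.loc[bad, 'call'].unique())}"
        )
    return df


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")


def crosstab(calls: pd.DataFrame, reference: pd.DataFrame) -> ConcordanceTable:
    """Cross-tabulate this method's calls (rows) against reference calls
    (columns), matched on snp_id; SNPs absent from either side are
    excluded and counted.  A ``genotype`` column in the reference (e.g. a
    simulator truth table) is accepted as an alias for ``call``."""
    if "call" not in reference.columns and "genotype" in reference.columns:
        reference = reference.rename(columns={"genotype": "call"})
    merged = calls[["snp_id", "call"]].merge(
        reference[["snp_id", "call"]], on="snp_id", suffixes=("", "_ref")
    )
    if len(merged) == 0:
        raise InputError("no overlapping snp_id between calls and reference")
    table = pd.crosstab(merged["call"], merged["call_ref"]).reindex(
        index=CALL_LABELS, columns=CALL_LABELS, fill_value=0
    )
    table.index.name = "call"
    table.columns.name = "reference"
    return ConcordanceTable(
        counts=table,
        n_compared=len(merged),
        n_only_calls=len(calls) - len(merged),
        n_only_reference=len(reference) - len(merged),
    )


def concordance_rate(table: ConcordanceTable) -> float:
    """Fraction of compared SNPs on the (AA, AB, BB) diagonal, among SNPs
    where both sides made a call."""
    sub = table.counts.loc[list(GENOTYPES), list(GENOTYPES)]
    total = sub.to_numpy().sum()
    if total == 0:
        return float("nan")
    return float(np.trace(sub.to_numpy()) / total)


def compute_maf(call_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-SNP B-allele frequency and minor allele frequency across arrays.

    f = (2 n_BB + n_AB) / (2 (n_AA + n_AB + n_BB)); MAF = min(f, 1 - f).
    NN calls are excluded; a SNP with no called genotype gets MAF = NaN.
    """
    if len(call_tables) == 0:
        raise InputError("need at least one call table")
    stacked = pd.concat(
        [t[["snp_id", "call"]] for t in call_tables], ignore_index=True
    )
    counts = (
        stacked.pivot_table(index="snp_id", columns="call", aggfunc="size", fill_value=0)
        .reindex(columns=list(CALL_LABELS), fill_value=0)
    )
    n_called = counts[list(GENOTYPES)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (2 * counts["BB"] + counts["AB"]) / (2 * n_called)
    maf = np.minimum(f, 1 - f)
    out = pd.DataFrame(
        {"snp_id": counts.index, "f_B": f.to_numpy(), "maf": maf.to_numpy(),
         "n_called": n_called.to_numpy()}
    ).reset_index(drop=True)
    out.loc[out["n_called"] == 0, ["f_B", "maf"]] = np.nan
    return out


def quality_summaries(call_tables: list[pd.DataFrame]) -> dict:
    """Calling-quality indicators across one or more arrays.

    Returns per-array P* quantiles, the per-SNP mean P* over arrays (a
    reasonable per-marker quality indicator), and per-SNP
    genotype-presence counts (how many distinct genotypes, 1-3, a SNP
    shows across arrays).
    """
    if len(call_tables) == 0:
        raise InputError("need at least one call table")
    per_array = pd.DataFrame(
        {
            "array": range(len(call_tables)),
            "median_pstar": [t["pstar"].median() for t in call_tables],
            "q10_pstar": [t["pstar"].quantile(0.10) for t in call_tables],
            "min_pstar": [t["pstar"].min() for t in call_tables],
        }
    )
    stacked = pd.concat(
        [t[["snp_id", "call", "pstar"]] for t in call_tables], ignore_index=True
    )
    called = stacked[stacked["call"].isin(GENOTYPES)]
    per_snp = called.groupby("snp_id").agg(
        mean_pstar=("pstar", "mean"),
        n_genotypes=("call", "nunique"),
        n_arrays=("call", "size"),
    ).reset_index()
    return {"per_array": per_array, "per_snp": per_snp}


def pstar_ecdf(pstar_values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of P* values; support lies within [1/3, 1]."""
    x = np.sort(np.asarray(pstar_values, float))
    return x, np.arange(1, len(x) + 1) / len(x)
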
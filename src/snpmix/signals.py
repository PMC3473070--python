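"""Transform raw two-allele fluorescence intensities to the (strength, contrast)
plane and build the initial three-sector partition that seeds the EM fit.

Each SNP on an array yields two fluorescence intensities, one per allele
(A and B, linear scale).  Working coordinates are

    strength = (log10 A + log10 B) / 2     -- overall signal level
    contrast = log10 B - log10 A           -- separates the genotypes

so the three genotype clusters form horizontal bands: AA at negative
contrast, AB around zero, BB at positive contrast.  Swapping the two
channels negates contrast and leaves strength unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError, ParseError

GENOTYPES = ("AA", "AB", "BB")
CALL_LABELS = ("AA", "AB", "BB", "NN")

#: default raw-scale floor applied to non-positive / missing intensities
DEFAULT_CLIP_FLOOR = 1.0


@dataclass(frozen=True)
class SeedPartition:
    """Hard three-sector split of the contrast axis used to start EM.

    Two horizontal lines at ``split_lo`` and ``split_hi`` divide the
    (strength, contrast) plane into AA (below), AB (middle, closed) and
    BB (above) sectors.  The exact positions are not critical.
    """

    split_lo: float
    split_hi: float
    labels: pd.Series  # per-SNP seed label in {AA, AB, BB}


def read_signals(path) -> pd.DataFrame:
    """Read a raw signal table (TSV with columns snp_id, signal_A, signal_B).

    Lines starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    missing = {"snp_id", "signal_A", "signal_B"} - set(df.columns)
    if missing:
        raise InputError(f"signal table missing columns: {sorted(missing)}")
    return df


def write_signals(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def transform_signals(
    raw: pd.DataFrame, clip_floor: float = DEFAULT_CLIP_FLOOR
) -> pd.DataFrame:
    """Map raw (signal_A, signal_B) pairs to (strength, contrast).

    Non-positive or missing intensities are clipped up to ``clip_floor``
    (raw scale) rather than dropped, so every SNP gets a call; the
    per-SNP ``clipped`` flag records when this happened.

    Returns a DataFrame with columns snp_id, strength, contrast, clipped.
    """
    if len(raw) == 0:
        raise InputError("empty signal table")
    if clip_floor <= 0:
        raise ConfigError(f"clip_floor must be > 0, got {clip_floor}")
    if raw["snp_id"].duplicated().any():
        dups = raw.loc[raw["snp_id"].duplicated(), "snp_id"].tolist()[:5]
        raise InputError(f"duplicate snp_id values, e.g. {dups}")

    def _as_float(col):
        s = raw[col]
        if pd.api.types.is_numeric_dtype(s):
            return s.to_numpy(float)
        return pd.to_numeric(s, errors="coerce").to_numpy(float)

    a = _as_float("signal_A")
    b = _as_float("signal_B")
    bad = ~np.isfinite(a) & raw["signal_A"].notna().to_numpy()
    bad |= ~np.isfinite(b) & raw["signal_B"].notna().to_numpy()
    if bad.any():
        ids = raw.loc[bad, "snp_id"].tolist()
        raise ParseError(
            f"non-numeric signal for {bad.sum()} SNP(s), e.g. {ids[:5]}", ids
        )

    a = np.nan_to_num(a, nan=0.0)
    b = np.nan_to_num(b, nan=0.0)
    clipped = (a < clip_floor) | (b < clip_floor)
    la = np.log10(np.maximum(a, clip_floor))
    lb = np.log10(np.maximum(b, clip_floor))
    return pd.DataFrame(
        {
            "snp_id": raw["snp_id"].to_numpy(),
            "strength": (la + lb) / 2.0,
            "contrast": lb - la,
            "clipped": clipped,
        }
    )


def seed_labels(
    transformed: pd.DataFrame, split_lo: float = -0.2, split_hi: float = 0.2
) -> SeedPartition:
    """Assign every SNP a seed genotype from its contrast sector.

    contrast < split_lo -> AA; split_lo <= contrast <= split_hi -> AB
    (closed middle sector, so boundary ties go to AB); contrast >
    split_hi -> BB.
    """
    if not split_lo < split_hi:
        raise ConfigError(f"split_lo ({split_lo}) must be < split_hi ({split_hi})")
    c = transformed["contrast"].to_numpy(float)
    labels = np.where(c < split_lo, "AA", np.where(c > split_hi, "BB", "AB"))
    return SeedPartition(
        split_lo=split_lo,
        split_hi=split_hi,
        labels=pd.Series(labels, index=transformed.index, name="seed_label"),
    )
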
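"""Reading, validating, genomic-control correction and merging of GWAS
summary statistics.

A summary-statistics set is represented as a :class:`pandas.DataFrame`
with the canonical columns ``snp_id`` (str), ``chrom`` (str, "chr"
prefix stripped), ``pos`` (int, 1-based) and ``pvalue`` (float in
(0, 1]), plus an optional ``zscore`` column.  A merged two-trait panel
carries ``snp_id, chrom, pos, p_i, p_j`` where trait *i* is the
principal trait and trait *j* the conditioning trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, ConfigError, InputError

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with one degree of freedom,
#: fixed to four decimals; the reference point of the genomic-control
#: inflation factor lambda.
CHI2_1_MEDIAN = 0.4549

#: Smallest representable p-value; smaller (or zero) p-values are clamped
#: here under the default policy so that chi-square transforms and log
#: scales stay finite.
P_FLOOR = 1e-300

SUMSTATS_COLUMNS = ("snp_id", "chrom", "pos", "pvalue")
MERGED_COLUMNS = ("snp_id", "chrom", "pos", "p_i", "p_j")

_AUTOSOMES = frozenset(str(c) for c in range(1, 23))


@dataclass(frozen=True)
class GcReport:
    """Genomic-control diagnostic for one summary-statistics set."""

    lambda_gc: float
    n_snps: int
    applied: bool = False


def _normalize_chrom(chrom: pd.Series) -> pd.Series:
    s = chrom.astype(str).str.strip()
    s = s.str.replace(r"^(?i:chr)", "", regex=True)
    return s.str.upper().str.replace(r"^23$", "X", regex=True)


def chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric sort key for chromosome labels (1..22, X=23, Y=24, MT=25)."""
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    out = pd.to_numeric(chrom, errors="coerce")
    mask = out.isna()
    out[mask] = chrom[mask].map(lambda c: special.get(str(c), 99))
    return out.astype(np.int64)


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    zero_policy: str = "clamp",
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Read one delimited summary-statistics file into canonical form.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Mapping from canonical names (``snp_id, chrom, pos, pvalue`` and
        optionally ``zscore``) to the column names used in the file.
        ``None`` assumes the file already uses canonical names.
    sep
        Field separator; ``None`` sniffs tab vs comma from the header.
    zero_policy
        ``"clamp"`` replaces p < 1e-300 (including 0) by 1e-300;
        ``"reject"`` drops such rows instead.
    autosomes_only
        Drop non-autosomal records (X, Y, MT); on by default since the
        analysis is restricted to chromosomes 1-22.

    Returns
    -------
    pandas.DataFrame
        Validated records; invalid rows are dropped and counted in the
        log, and duplicated ``snp_id`` keeps the smallest p-value.
    """
    if zero_policy not in ("clamp", "reject"):
        raise ConfigError(f"zero_policy must be 'clamp' or 'reject', got {zero_policy!r}")
    dialect = dict(dialect or {})
    for key in dialect:
        if key not in ("snp_id", "chrom", "pos", "pvalue", "zscore"):
            raise ConfigError(f"unknown dialect key {key!r}")

    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    colmap = {name: dialect.get(name, name) for name in SUMSTATS_COLUMNS}
    if "zscore" in dialect or (not dialect and "zscore" in raw.columns):
        colmap["zscore"] = dialect.get("zscore", "zscore")
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise ConfigError(f"mapped column(s) {missing} not found in {path}")

    df = pd.DataFrame({name: raw[src] for name, src in colmap.items()})
    n_raw = len(df)

    df["snp_id"] = df["snp_id"].astype(str).str.strip()
    df["chrom"] = _normalize_chrom(df["chrom"])
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    if "zscore" in df.columns:
        df["zscore"] = pd.to_numeric(df["zscore"], errors="coerce")

    valid = (
        df["snp_id"].str.len().gt(0)
        & df["pos"].notna()
        & (df["pos"] > 0)
        & df["pvalue"].notna()
        & (df["pvalue"] <= 1.0)
    )
    if zero_policy == "clamp":
        valid &= df["pvalue"] >= 0.0
    else:
        valid &= df["pvalue"] >= P_FLOOR
    df = df[valid].copy()
    df["pvalue"] = df["pvalue"].clip(lower=P_FLOOR)
    df["pos"] = df["pos"].astype(np.int64)

    if autosomes_only:
        df = df[df["chrom"].isin(_AUTOSOMES)]

    if "zscore" in df.columns and df["zscore"].notna().any():
        both = df["zscore"].notna()
        implied = 2.0 * stats.norm.sf(np.abs(df.loc[both, "zscore"]))
        consistent = np.abs(implied - df.loc[both, "pvalue"]) <= 1e-6 * df.loc[both, "pvalue"]
        bad = both.copy()
        bad.loc[both] = ~consistent
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning("%s: dropped %d rows with inconsistent z/p", path, n_bad)
            df = df[~bad]

    # duplicates: keep the smallest p-value, deterministically
    df = df.sort_values(["pvalue", "snp_id"], kind="mergesort")
    df = df.drop_duplicates("snp_id", keep="first")
    df = df.sort_values(["chrom", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)

    n_dropped = n_raw - len(df)
    logger.info("%s: read %d rows, kept %d (%d dropped)", path, n_raw, len(df), n_dropped)
    if len(df) == 0:
        raise InputError(f"no valid rows in {path}")
    return df


def estimate_lambda_gc(stats_df: pd.DataFrame) -> GcReport:
    """Genomic-control inflation factor of one summary-statistics set.

    lambda = median(chi2_1 quantile transform of the p-values) / 0.4549.
    Under the null the transform is a chi-square(1) sample and lambda is
    1; population stratification inflates it above 1.
    """
    p = np.asarray(stats_df["pvalue"], dtype=float)
    if p.size == 0:
        raise InputError("cannot estimate lambda on an empty set")
    if np.any(p <= 0.0):
        raise ComputationError("p-values must be strictly positive for lambda estimation")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    return GcReport(lambda_gc=lam, n_snps=int(p.size), applied=False)


def apply_genomic_control(stats_df: pd.DataFrame, lambda_gc: float) -> pd.DataFrame:
    """Deflate p-values by the genomic-control factor.

    Each p is mapped through the chi-square(1) scale: the corrected
    value is the tail probability of chi2/lambda.  lambda <= 1 leaves
    the input unchanged (correction never makes p-values smaller).
    """
    if lambda_gc <= 0:
        raise ConfigError(f"lambda_gc must be positive, got {lambda_gc}")
    out = stats_df.copy()
    if lambda_gc <= 1.0:
        return out
    chi2 = stats.chi2.isf(out["pvalue"].to_numpy(dtype=float), df=1)
    out["pvalue"] = np.clip(stats.chi2.sf(chi2 / lambda_gc, df=1), P_FLOOR, 1.0)
    return out


def merge_on_snp(principal: pd.DataFrame, conditioning: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two summary-statistics sets on ``snp_id``.

    The result carries coordinates from the principal-trait file and is
    ordered by (chromosome, position).  Only SNPs present in both inputs
    survive; intersection and exclusion counts are logged.
    """
    left = principal[["snp_id", "chrom", "pos", "pvalue"]].rename(columns={"pvalue": "p_i"})
    right = conditioning[["snp_id", "pvalue"]].rename(columns={"pvalue": "p_j"})
    merged = left.merge(right, on="snp_id", how="inner")
    if len(merged) == 0:
        raise InputError("no shared SNP identifiers between the two datasets")
    merged["_ckey"] = chrom_sort_key(merged["chrom"])
    merged = merged.sort_values(["_ckey", "pos", "snp_id"], kind="mergesort")
    merged = merged.drop(columns="_ckey").reset_index(drop=True)
    logger.info(
        "merged %d shared SNPs (principal %d, conditioning %d; excluded %d / %d)",
        len(merged), len(principal), len(conditioning),
        len(principal) - len(merged), len(conditioning) - len(merged),
    )
    return merged[list(MERGED_COLUMNS)]


def write_merged(merged: pd.DataFrame, path: str | Path) -> None:
    """Write a merged panel as TSV (snp_id, chrom, pos, p_i, p_j)."""
    merged.to_csv(path, sep="\t", index=False, float_format="%.6G")
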
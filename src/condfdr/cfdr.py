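"""Empirical conditional FDR (cFDR) and conjunctional cFDR (ccFDR).

The conditional FDR of a SNP for a principal trait *i* given a
conditioning trait *j* is the posterior probability that the SNP is
null for trait *i* given that both of its p-values are at or below the
observed pair.  Its empirical-Bayes estimate from a merged panel is the
count-ratio

    cFDR(p_i | p_j) = p_i * N(P_j <= p_j) / N(P_i <= p_i, P_j <= p_j),

capped at 1, where the counts run over all SNPs of the panel and each
query SNP counts itself (so the denominator is at least 1).  The
conjunctional cFDR combines the two conditioning directions as

    ccFDR = max( cFDR(p_i | p_j), cFDR(p_j | p_i) ),

the posterior probability that the SNP is null for at least one of the
two traits; SNPs with ccFDR below the significance level are the
pleiotropic candidates.

Per-SNP values are computed by exact counting at the observed p-value
pairs (sorting + a Fenwick-tree sweep, O(n log n)); the rectangular
look-up tables mirror the same counts on a threshold grid and exist for
export and visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._dominance import joint_dominance_counts
from .errors import ConfigError
from .sumstats import MERGED_COLUMNS

RESULT_COLUMNS = (
    "snp_id", "chrom", "pos", "p_i", "p_j",
    "cfdr_i_given_j", "cfdr_j_given_i", "ccfdr",
)


@dataclass(frozen=True)
class CfdrTable:
    """cFDR estimates on a rectangular (p_i, p_j) threshold grid."""

    pi_grid: np.ndarray
    pj_grid: np.ndarray
    values: np.ndarray  # shape (len(pi_grid), len(pj_grid))
    monotonized: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{t:.6G}" for t in self.pj_grid])
        df.insert(0, "p_i", self.pi_grid)
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4G")


def cfdr_values(p_i: np.ndarray, p_j: np.ndarray) -> np.ndarray:
    """Vector of cFDR(p_i | p_j) at every observed pair of the panel."""
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    n_j = np.searchsorted(np.sort(p_j), p_j, side="right")
    n_ij = joint_dominance_counts(p_i, p_j)
    return np.minimum(p_i * n_j / n_ij, 1.0)


def empirical_cfdr(merged: pd.DataFrame, p_i_star: float, p_j_star: float) -> float:
    """cFDR estimate at a single query point (p_i*, p_j*).

    For a query off the observed panel the joint count can be zero; the
    estimate then defaults to 1 (most conservative) with a warning.
    """
    if not (0.0 < p_i_star <= 1.0 and 0.0 < p_j_star <= 1.0):
        raise ConfigError("query p-values must lie in (0, 1]")
    p_i = merged["p_i"].to_numpy(dtype=float)
    p_j = merged["p_j"].to_numpy(dtype=float)
    n_j = int(np.count_nonzero(p_j <= p_j_star))
    n_ij = int(np.count_nonzero((p_i <= p_i_star) & (p_j <= p_j_star)))
    if n_ij == 0:
        warnings.warn(
            "empty joint count at query point; returning the conservative value 1",
            stacklevel=2,
        )
        return 1.0
    return min(p_i_star * n_j / n_ij, 1.0)


def unconditional_fdr(p_i: np.ndarray, monotone: bool = False) -> np.ndarray:
    """Empirical FDR without conditioning: cFDR at p_j = 1.

    The raw value for the SNP of rank r (1-based, ties counted with <=)
    is ``p * n / r``; with ``monotone=True`` a running minimum from the
    least significant end turns it into the familiar step-up adjusted
    p-value.
    """
    p_i = np.asarray(p_i, dtype=float)
    ranks = np.searchsorted(np.sort(p_i), p_i, side="right")
    vals = np.minimum(p_i * p_i.size / ranks, 1.0)
    if monotone:
        order = np.argsort(p_i, kind="mergesort")
        adj = np.minimum.accumulate(vals[order][::-1])[::-1]
        out = np.empty_like(vals)
        out[order] = adj
        return out
    return vals


def build_lookup_table(
    merged: pd.DataFrame, pi_grid: np.ndarray, pj_grid: np.ndarray
) -> CfdrTable:
    """Evaluate the cFDR estimator on a rectangular threshold grid.

    Every cell equals a pointwise :func:`empirical_cfdr` call; cells
    whose joint count is zero take the conservative value 1.
    """
    pi_grid = np.asarray(pi_grid, dtype=float)
    pj_grid = np.asarray(pj_grid, dtype=float)
    if pi_grid.size == 0 or pj_grid.size == 0:
        raise ConfigError("lookup-table grids must be non-empty")
    if np.any((pi_grid <= 0) | (pi_grid > 1)) or np.any((pj_grid <= 0) | (pj_grid > 1)):
        raise ConfigError("grid thresholds must lie in (0, 1]")

    p_i = merged["p_i"].to_numpy(dtype=float)
    p_j = merged["p_j"].to_numpy(dtype=float)
    values = np.ones((pi_grid.size, pj_grid.size))
    for col, pj_thr in enumerate(pj_grid):
        mask = p_j <= pj_thr
        n_j = int(mask.sum())
        if n_j == 0:
            continue
        stratum = np.sort(p_i[mask])
        n_ij = np.searchsorted(stratum, pi_grid, side="right")
        ok = n_ij > 0
        values[ok, col] = np.minimum(pi_grid[ok] * n_j / n_ij[ok], 1.0)
    return CfdrTable(pi_grid=pi_grid, pj_grid=pj_grid, values=values, monotonized=False)


def monotonize(table: CfdrTable) -> CfdrTable:
    """Enforce monotonicity in p_i within each conditioning column.

    A smaller p_i must never carry a larger cFDR than a larger p_i at
    the same conditioning threshold; the running minimum is taken from
    the least-significant end of each column toward the most
    significant, so values only decrease or stay equal.
    """
    order = np.argsort(table.pi_grid, kind="mergesort")  # increasing p_i
    values = table.values.copy()
    sub = values[order][::-1]
    sub = np.minimum.accumulate(sub, axis=0)[::-1]
    values[order] = sub
    return replace(table, values=values, monotonized=True)


def assign_cfdr(merged: pd.DataFrame, monotone: bool = False, strata=None) -> pd.DataFrame:
    """Per-SNP cFDR in both conditioning directions plus the ccFDR.

    Parameters
    ----------
    merged
        Panel with columns ``snp_id, chrom, pos, p_i, p_j``.
    monotone
        When true, each directional value is additionally monotonized
        along ranked principal p within conditioning-stratum bins; the
        default reports the raw count-ratio estimates.
    strata
        Conditioning bin edges used only when ``monotone`` is true
        (default: decades 1, 0.1, ..., 1e-4).

    Returns
    -------
    pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, p_i, p_j,
        cfdr_i_given_j, cfdr_j_given_i, ccfdr`` in the input order.
    """
    missing = [c for c in MERGED_COLUMNS if c not in merged.columns]
    if missing:
        raise ConfigError(f"merged panel lacks column(s) {missing}")
    p_i = merged["p_i"].to_numpy(dtype=float)
    p_j = merged["p_j"].to_numpy(dtype=float)
    c_ij = cfdr_values(p_i, p_j)
    c_ji = cfdr_values(p_j, p_i)
    if monotone:
        edges = np.asarray(strata if strata is not None else [1.0, 0.1, 0.01, 1e-3, 1e-4])
        c_ij = _monotone_within_bins(p_i, p_j, c_ij, edges)
        c_ji = _monotone_within_bins(p_j, p_i, c_ji, edges)
    out = merged[["snp_id", "chrom", "pos", "p_i", "p_j"]].copy()
    out["cfdr_i_given_j"] = c_ij
    out["cfdr_j_given_i"] = c_ji
    out["ccfdr"] = np.maximum(c_ij, c_ji)
    return out


def _monotone_within_bins(p_prin, p_cond, vals, edges) -> np.ndarray:
    edges = np.sort(np.asarray(edges, dtype=float))
    bins = np.searchsorted(edges, p_cond, side="left")
    out = vals.copy()
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        order = idx[np.argsort(p_prin[idx], kind="mergesort")]
        out[order] = np.minimum.accumulate(out[order][::-1])[::-1]
    return out


def significant_set(results: pd.DataFrame, field: str = "ccfdr", alpha: float = 0.05) -> set[str]:
    """SNP ids whose chosen statistic is strictly below ``alpha``."""
    if field not in ("cfdr_i_given_j", "cfdr_j_given_i", "ccfdr"):
        raise ConfigError(f"unknown statistic field {field!r}")
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    mask = results[field].to_numpy(dtype=float) < alpha
    return set(results.loc[mask, "snp_id"])


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Per-SNP results as TSV with 4-significant-digit scientific floats."""
    out = results.copy()
    for col in ("p_i", "p_j", "cfdr_i_given_j", "cfdr_j_given_i", "ccfdr"):
        out[col] = out[col].map(lambda v: f"{v:.3E}")
    out.to_csv(path, sep="\t", index=False)
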
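"""Stratified Q-Q, fold-enrichment and stratified TDR diagnostics.

Pleiotropic enrichment between two traits shows up as a leftward shift
of the principal trait's Q-Q curve within SNP strata selected by the
conditioning trait's significance.  Strata are nested: the defaults
condition at p_j <= 1 (all SNPs), 0.1, 0.01, 1e-3 and 1e-4, matching
the -log10 cutoffs 0..4.  Fold-enrichment divides a stratum's empirical
exceedance proportion by the all-SNP proportion, and the stratified TDR
curve is one minus the cFDR estimate at each (nominal p, stratum
cutoff) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComputationError, ConfigError
from . import cfdr as _cfdr

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1.0, 0.1, 0.01, 1e-3, 1e-4)


@dataclass(frozen=True)
class StratumSpec:
    """Nested conditioning strata: decreasing p_j cutoffs, first is 1."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_size: int = 100

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) == 0 or t[0] != 1.0:
            raise ConfigError("the first stratum must be the all-SNP cutoff 1")
        if any(not 0.0 < x <= 1.0 for x in t):
            raise ConfigError("stratum cutoffs must lie in (0, 1]")
        if any(b >= a for a, b in zip(t, t[1:])):
            raise ConfigError("stratum cutoffs must be strictly decreasing")
        if self.min_size < 1:
            raise ConfigError("min_size must be positive")


@dataclass(frozen=True)
class QQCurve:
    stratum: float
    nominal_neglog: np.ndarray
    empirical_neglog: np.ndarray
    n_in_stratum: int


@dataclass(frozen=True)
class FoldCurve:
    stratum: float
    nominal_neglog: np.ndarray
    fold: np.ndarray  # NaN where the all-SNP proportion is zero
    n_in_stratum: int


@dataclass(frozen=True)
class TdrCurve:
    stratum: float
    nominal_neglog: np.ndarray
    tdr: np.ndarray
    n_in_stratum: int


def default_grid(n_points: int = 1000, max_neglog: float = 10.0) -> np.ndarray:
    """Nominal p grid: equally spaced in -log10 p over [0, max_neglog]."""
    return 10.0 ** -np.linspace(0.0, max_neglog, n_points)


def _stratum_proportions(p_i, p_j, spec, grid):
    """Per stratum: (cutoff, n, exceedance proportion at each grid p)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any((grid <= 0) | (grid > 1)):
        raise ConfigError("nominal grid must lie in (0, 1]")
    rows = []
    for cutoff in spec.thresholds:
        mask = p_j <= cutoff
        n = int(mask.sum())
        if n < spec.min_size:
            logger.warning("stratum p_j<=%g has %d SNPs (<%d), skipped", cutoff, n, spec.min_size)
            rows.append((cutoff, n, None))
            continue
        sorted_pi = np.sort(p_i[mask])
        q = np.searchsorted(sorted_pi, grid, side="right") / n
        rows.append((cutoff, n, q))
    if all(q is None for _, _, q in rows):
        raise ComputationError("every stratum is below the minimum size")
    return grid, rows


def stratified_qq(
    merged: pd.DataFrame, spec: StratumSpec | None = None, grid: np.ndarray | None = None
) -> list[QQCurve]:
    """Stratified Q-Q curves of the principal trait conditional on p_j.

    For each stratum the empirical quantile q(t) is the proportion of
    stratum SNPs with p_i <= t, reported on the -log10 scale; q = 0
    maps to +inf.  Strata below the minimum size are skipped with a
    warning.
    """
    spec = spec or StratumSpec()
    grid, rows = _stratum_proportions(
        merged["p_i"].to_numpy(dtype=float), merged["p_j"].to_numpy(dtype=float), spec,
        default_grid() if grid is None else grid,
    )
    neglog_t = -np.log10(grid)
    curves = []
    for cutoff, n, q in rows:
        if q is None:
            continue
        with np.errstate(divide="ignore"):
            curves.append(QQCurve(cutoff, neglog_t, -np.log10(q), n))
    return curves


def fold_enrichment(
    merged: pd.DataFrame, spec: StratumSpec | None = None, grid: np.ndarray | None = None
) -> list[FoldCurve]:
    """Fold-enrichment curves: q_stratum(t) / q_all(t) per stratum.

    Grid points where the all-SNP proportion is zero are reported as
    NaN (missing), never as infinity.  The all-SNP stratum's curve is
    identically 1 wherever defined.
    """
    spec = spec or StratumSpec()
    grid, rows = _stratum_proportions(
        merged["p_i"].to_numpy(dtype=float), merged["p_j"].to_numpy(dtype=float), spec,
        default_grid() if grid is None else grid,
    )
    q_all = rows[0][2]
    if q_all is None:
        raise ComputationError("the all-SNP stratum is below the minimum size")
    neglog_t = -np.log10(grid)
    curves = []
    for cutoff, n, q in rows:
        if q is None:
            continue
        fold = np.full_like(q, np.nan)
        ok = q_all > 0
        fold[ok] = q[ok] / q_all[ok]
        curves.append(FoldCurve(cutoff, neglog_t, fold, n))
    return curves


def stratified_tdr(
    merged: pd.DataFrame, spec: StratumSpec | None = None, grid: np.ndarray | None = None
) -> list[TdrCurve]:
    """Stratified true-discovery-rate curves, TDR = 1 - cFDR.

    The cFDR estimate at (t, cutoff) is the count-ratio of the cFDR
    engine evaluated on the grid; empty joint counts give cFDR 1 and
    hence TDR 0 (conservative).
    """
    spec = spec or StratumSpec()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    p_j = merged["p_j"].to_numpy(dtype=float)
    table = _cfdr.build_lookup_table(merged, grid, np.asarray(spec.thresholds))
    neglog_t = -np.log10(grid)
    curves = []
    for col, cutoff in enumerate(spec.thresholds):
        n = int((p_j <= cutoff).sum())
        if n < spec.min_size:
            logger.warning("stratum p_j<=%g has %d SNPs (<%d), skipped", cutoff, n, spec.min_size)
            continue
        tdr = np.clip(1.0 - table.values[:, col], 0.0, 1.0)
        curves.append(TdrCurve(cutoff, neglog_t, tdr, n))
    if not curves:
        raise ComputationError("every stratum is below the minimum size")
    return curves


def curves_to_frame(curves) -> pd.DataFrame:
    """Tidy (stratum, x, y, n) table for any plotting front-end."""
    frames = []
    for c in curves:
        y = getattr(c, "empirical_neglog", None)
        if y is None:
            y = getattr(c, "fold", None)
        if y is None:
            y = c.tdr
        frames.append(
            pd.DataFrame(
                {"stratum": c.stratum, "x": c.nominal_neglog, "y": y, "n": c.n_in_stratum}
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_curves(curves, path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, sep="\t", index=False, float_format="%.6G")


def random_prune(merged: pd.DataFrame, window_kb: float = 250.0, seed: int = 0) -> pd.DataFrame:
    """Keep one random SNP per non-overlapping genomic window.

    A sensitivity-analysis aid for panels with correlated neighbouring
    SNPs; the diagnostics themselves never prune by default.
    """
    rng = np.random.default_rng(seed)
    window = int(window_kb * 1000)
    key = merged["chrom"].astype(str) + ":" + (merged["pos"] // window).astype(str)
    pick = (
        pd.Series(rng.random(len(merged)), index=merged.index)
        .groupby(key.to_numpy())
        .idxmax()
    )
    return merged.loc[sorted(pick)].reset_index(drop=True)


def plot_curves(curves, ax=None, ylabel: str = "y"):
    """Render curves with matplotlib; returns the axis (convenience only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        y = curves_to_frame([c])["y"]
        ax.plot(c.nominal_neglog, y, label=f"p_j <= {c.stratum:g}")
    ax.set_xlabel("nominal -log10 p")
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax
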
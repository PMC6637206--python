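"""Synthetic paired GWAS summary statistics with known ground truth.

Two traits are simulated at the z-score level under a four-component
mixture: each SNP is null for both traits, associated with trait 1
only, with trait 2 only, or with both (pleiotropic).  Per component the
z-score pair is bivariate normal,

    z ~ N(0, C_null + C_effect),

where ``C_null = [[1, rho_null], [rho_null, 1]]`` models shared noise
from overlapping samples, and ``C_effect`` adds ``sigma1_sq`` and/or
``sigma2_sq`` on the diagonal with a cross term
``rho_pleio * sigma1 * sigma2`` for pleiotropic SNPs.  An optional
genomic-inflation factor multiplies the total variance, and an optional
block-exchangeable mode correlates consecutive SNPs to imitate linkage
disequilibrium for the locus-clumping stage.  Two-sided p-values are
``p = 2 * Phi(-|z|)``.

The generator is the ground-truth oracle for the rest of the package:
the per-SNP component labels say which null hypotheses are true, so
false-discovery proportions of any declared SNP set can be computed
exactly with :func:`truth_fdp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError
from .sumstats import P_FLOOR

COMPONENTS = ("null", "trait1", "trait2", "pleiotropic")


@dataclass
class GeneratorConfig:
    """Study-scale defaults for the two-trait mixture generator.

    The default mixture is a sparse polygenic regime: 10^5 SNPs of
    which 1% are associated with each single trait and 0.1% with both,
    with non-null z-score variance 16 (i.e. mean chi-square 17 for
    causal SNPs, a moderately powered meta-analysis), independent null
    noise and no inflation.
    """

    n_snps: int = 100_000
    pi0: float = 0.979
    pi1: float = 0.01
    pi2: float = 0.01
    pi12: float = 0.001
    sigma1_sq: float = 16.0
    sigma2_sq: float = 16.0
    rho_null: float = 0.0
    rho_pleio: float = 0.5
    lambda_inflation: float = 1.0
    seed: int = 0
    n_chrom: int = 22
    # optional block-exchangeable correlation imitating LD
    block_size: int = 1
    block_r: float = 0.0

    def __post_init__(self) -> None:
        props = (self.pi0, self.pi1, self.pi2, self.pi12)
        if any(p < 0 for p in props):
            raise ConfigError("mixture proportions must be nonnegative")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ConfigError(f"mixture proportions must sum to 1, got {sum(props)!r}")
        if self.sigma1_sq < 0 or self.sigma2_sq < 0:
            raise ConfigError("effect variances must be nonnegative")
        if not 0.0 <= self.rho_null < 1.0:
            raise ConfigError("rho_null must be in [0, 1)")
        if not -1.0 <= self.rho_pleio <= 1.0:
            raise ConfigError("rho_pleio must be in [-1, 1]")
        if self.lambda_inflation < 1.0:
            raise ConfigError("lambda_inflation must be >= 1")
        if self.n_snps < 1 or self.n_chrom < 1:
            raise ConfigError("n_snps and n_chrom must be positive")
        if self.block_size < 1 or not 0.0 <= self.block_r < 1.0:
            raise ConfigError("block_size must be >= 1 and block_r in [0, 1)")


def _draw_z(components: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw one bivariate z pair per entry of ``components`` (no inflation)."""
    n = components.shape[0]
    e = rng.standard_normal((n, 2))
    z = np.empty_like(e)
    z[:, 0] = e[:, 0]
    z[:, 1] = cfg.rho_null * e[:, 0] + math.sqrt(1.0 - cfg.rho_null**2) * e[:, 1]

    s1 = math.sqrt(cfg.sigma1_sq)
    s2 = math.sqrt(cfg.sigma2_sq)
    m1 = components == 1
    if m1.any():
        z[m1, 0] += s1 * rng.standard_normal(int(m1.sum()))
    m2 = components == 2
    if m2.any():
        z[m2, 1] += s2 * rng.standard_normal(int(m2.sum()))
    m12 = components == 3
    if m12.any():
        k = int(m12.sum())
        u = rng.standard_normal((k, 2))
        z[m12, 0] += s1 * u[:, 0]
        z[m12, 1] += s2 * (cfg.rho_pleio * u[:, 0] + math.sqrt(1.0 - cfg.rho_pleio**2) * u[:, 1])
    return z


def _layout(cfg: GeneratorConfig, rng: np.random.Generator, n_blocks: int) -> pd.DataFrame:
    """Chromosome/position layout; members of an LD block sit 1 kb apart."""
    chrom = rng.integers(1, cfg.n_chrom + 1, size=n_blocks)
    base = rng.integers(1, 250_000_000, size=n_blocks)
    block = np.repeat(np.arange(n_blocks), cfg.block_size)[: cfg.n_snps]
    offset = (np.arange(cfg.n_snps) - np.searchsorted(block, block)) * 1_000
    return pd.DataFrame(
        {
            "chrom": chrom[block].astype(str),
            "pos": base[block] + offset,
            "block": block,
        }
    )


def generate_pair(
    cfg: GeneratorConfig, labels: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate paired summary statistics and their truth labels.

    Parameters
    ----------
    cfg
        Generator configuration; ``cfg.seed`` fixes the whole draw.
    labels
        Optional truth labels from a previous call.  When given, the
        mixture components (and SNP coordinates) are reused and only the
        z-scores are redrawn — an independent replication study of the
        same underlying signals.

    Returns
    -------
    (trait1, trait2, truth)
        Two canonical summary-statistics frames (``snp_id, chrom, pos,
        pvalue, zscore``) and a truth frame (``snp_id, component``).
    """
    rng = np.random.default_rng(cfg.seed)
    n_blocks = -(-cfg.n_snps // cfg.block_size)

    if labels is None:
        comp_blocks = rng.choice(4, size=n_blocks, p=[cfg.pi0, cfg.pi1, cfg.pi2, cfg.pi12])
        layout = _layout(cfg, rng, n_blocks)
        components = comp_blocks[layout["block"].to_numpy()]
        layout = layout.assign(component=components)
        layout = layout.sort_values(["chrom", "pos"], key=_sortable, kind="mergesort")
        layout = layout.reset_index(drop=True)
        layout["snp_id"] = [f"rs{i + 1:07d}" for i in range(cfg.n_snps)]
    else:
        required = {"snp_id", "chrom", "pos", "component", "block"}
        if not required.issubset(labels.columns):
            raise InputError("labels frame must come from a previous generate_pair call")
        layout = labels.reset_index(drop=True)

    comp = layout["component"]
    if comp.dtype == object:  # reused truth frame stores component names
        comp = comp.map({name: code for code, name in enumerate(COMPONENTS)})
    comp_codes = comp.to_numpy(dtype=np.int64)

    if cfg.block_size > 1:
        # z = sqrt(r) * block core + sqrt(1 - r) * per-SNP draw, both from
        # the component covariance, preserving every marginal moment
        block_of = layout["block"].to_numpy()
        order = np.argsort(block_of, kind="mergesort")
        first = np.zeros(len(block_of), dtype=bool)
        first[order[np.unique(block_of[order], return_index=True)[1]]] = True
        core_comp = comp_codes[first]
        core = _draw_z(core_comp, cfg, rng)
        core_by_block = np.zeros((block_of.max() + 1, 2))
        core_by_block[block_of[first]] = core
        indiv = _draw_z(comp_codes, cfg, rng)
        z = math.sqrt(cfg.block_r) * core_by_block[block_of] + math.sqrt(1 - cfg.block_r) * indiv
    else:
        z = _draw_z(comp_codes, cfg, rng)

    z *= math.sqrt(cfg.lambda_inflation)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)

    base = layout[["snp_id", "chrom", "pos"]]
    trait1 = base.assign(pvalue=p[:, 0], zscore=z[:, 0])
    trait2 = base.assign(pvalue=p[:, 1], zscore=z[:, 1])
    truth = layout[["snp_id", "chrom", "pos", "block"]].assign(
        component=[COMPONENTS[c] for c in comp_codes]
    )
    return trait1, trait2, truth


def _sortable(col: pd.Series) -> pd.Series:
    if col.name == "chrom":
        return pd.to_numeric(col, errors="coerce").fillna(99).astype(int)
    return col


def truth_fdp(declared: set[str] | list[str], truth: pd.DataFrame, trait: str) -> float:
    """Exact false-discovery proportion of a declared SNP set.

    ``trait`` is ``"trait1"``, ``"trait2"`` or ``"conjunction"``.  For a
    single trait the null holds unless the SNP's component involves that
    trait; for the conjunction the null holds unless the SNP is
    pleiotropic.  An empty declared set has FDP 0 by convention.
    """
    if trait not in ("trait1", "trait2", "conjunction"):
        raise ConfigError(f"unknown trait {trait!r}")
    declared = set(declared)
    if not declared:
        return 0.0
    comp = truth.set_index("snp_id")["component"]
    unknown = declared - set(comp.index)
    if unknown:
        raise InputError(f"{len(unknown)} declared SNP(s) not in the generated panel")
    labels = comp.loc[sorted(declared)]
    if trait == "trait1":
        null = labels.isin(("null", "trait2"))
    elif trait == "trait2":
        null = labels.isin(("null", "trait1"))
    else:
        null = labels != "pleiotropic"
    return float(null.mean())


def write_pair(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the generated pair in the TSV dialect the reader accepts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trait1": outdir / "trait1.tsv",
        "trait2": outdir / "trait2.tsv",
        "truth": outdir / "truth.tsv",
    }
    cols = ["snp_id", "chrom", "pos", "pvalue", "zscore"]
    trait1[cols].to_csv(paths["trait1"], sep="\t", index=False, float_format="%.10G")
    trait2[cols].to_csv(paths["trait2"], sep="\t", index=False, float_format="%.10G")
    truth[["snp_id", "component"]].to_csv(paths["truth"], sep="\t", index=False)
    return paths
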
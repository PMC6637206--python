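"""End-to-end discovery + replication workflow.

One run configuration drives the whole analysis: load (or simulate)
two summary-statistics sets, merge them on shared SNPs, produce the
enrichment diagnostics, estimate per-SNP cFDR/ccFDR, export look-up
tables and Manhattan-plot tables, clump significant SNPs into loci,
and optionally cross-check the loci against an independent replication
dataset.  All outputs are TSV/JSON; a manifest records the
configuration hash and the seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cfdr as _cfdr
from . import enrichment as _enr
from . import loci as _loci
from . import simulate as _sim
from . import sumstats as _ss
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

#: -log10(0.05): the significance line drawn on Manhattan plots.
MANHATTAN_THRESHOLD = float(-np.log10(0.05))


@dataclass
class RunConfig:
    """Everything one discovery/replication run needs.

    Either ``generator`` (synthetic mode) or the three file paths with
    their column dialects must be provided.  ``alpha`` is the cFDR
    significance level, ``strata`` the conditioning cutoffs of the
    diagnostics, ``clump_window_kb`` the locus window.
    """

    output_dir: str = "condfdr_out"
    seed: int = 0
    alpha: float = 0.05
    strata: tuple[float, ...] = _enr.DEFAULT_THRESHOLDS
    clump_window_kb: float = 1000.0
    r2_clump: float | None = None
    r2_replication: float = _loci.DEFAULT_R2_REPLICATION
    gc_correction: bool = False
    ld_path: str | None = None
    min_overlap: int = 100

    # file mode
    principal_path: str | None = None
    conditioning_path: str | None = None
    replication_path: str | None = None
    principal_dialect: dict | None = None
    conditioning_dialect: dict | None = None
    replication_dialect: dict | None = None

    # synthetic mode
    generator: _sim.GeneratorConfig | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.generator is None and (self.principal_path is None or self.conditioning_path is None):
            raise ConfigError("either a generator config or input file paths are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            gen = _sim.GeneratorConfig(**gen)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(generator=gen, **raw)

    def digest(self) -> str:
        """Stable hash of the scientific settings (paths excluded)."""
        d = dataclasses.asdict(self)
        for key in ("output_dir",):
            d.pop(key, None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class DiscoveryBundle:
    """In-memory artifacts of a discovery run."""

    merged: pd.DataFrame
    results: pd.DataFrame
    loci_principal: list
    loci_conditioning: list
    loci_conjunction: list
    conditioning_stats: pd.DataFrame
    truth: pd.DataFrame | None
    counts: dict
    paths: dict


def _load_inputs(config: RunConfig, outdir: Path):
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        trait1, trait2, truth = _sim.generate_pair(gen)
        _sim.write_pair(trait1, trait2, truth, outdir / "inputs")
        return trait1, trait2, truth
    trait1 = _ss.read_sumstats(config.principal_path, config.principal_dialect)
    trait2 = _ss.read_sumstats(config.conditioning_path, config.conditioning_dialect)
    return trait1, trait2, None


def _manhattan_frame(results: pd.DataFrame, column: str) -> pd.DataFrame:
    vals = results[column].to_numpy(dtype=float)
    out = results[["snp_id", "chrom", "pos"]].copy()
    out["neglog10"] = -np.log10(vals)
    out["above_threshold"] = out["neglog10"] > MANHATTAN_THRESHOLD
    return out


def run_discovery(config: RunConfig) -> DiscoveryBundle:
    """Execute merge -> diagnostics -> cFDR -> ccFDR -> clumping.

    Writes curve tables, both directional look-up tables, per-SNP
    results, conditional and conjunctional Manhattan tables, loci
    tables and a JSON manifest into ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    counts: dict[str, int | float] = {}

    trait1, trait2, truth = _load_inputs(config, outdir)
    counts["n_principal"] = len(trait1)
    counts["n_conditioning"] = len(trait2)

    for name, df in (("principal", trait1), ("conditioning", trait2)):
        rep = _ss.estimate_lambda_gc(df)
        counts[f"lambda_gc_{name}"] = rep.lambda_gc
        logger.info("lambda_gc(%s) = %.4f over %d SNPs", name, rep.lambda_gc, rep.n_snps)
    if config.gc_correction:
        trait1 = _ss.apply_genomic_control(trait1, counts["lambda_gc_principal"])
        trait2 = _ss.apply_genomic_control(trait2, counts["lambda_gc_conditioning"])

    merged = _ss.merge_on_snp(trait1, trait2)
    counts["n_merged"] = len(merged)

    spec = _enr.StratumSpec(thresholds=tuple(config.strata))
    for label, fn in (("qq", _enr.stratified_qq), ("fold", _enr.fold_enrichment),
                      ("tdr", _enr.stratified_tdr)):
        curves = fn(merged, spec)
        paths[f"curves_{label}"] = outdir / f"curves_{label}.tsv"
        _enr.write_curves(curves, paths[f"curves_{label}"])
    for cutoff in config.strata:
        counts[f"n_stratum_{cutoff:g}"] = int((merged["p_j"] <= cutoff).sum())

    results = _cfdr.assign_cfdr(merged)
    paths["results"] = outdir / "cfdr_results.tsv"
    _cfdr.write_results(results, paths["results"])

    pi_grid = 10.0 ** -np.linspace(0.0, 8.0, 33)
    pj_grid = np.asarray(config.strata, dtype=float)
    swapped = merged.rename(columns={"p_i": "p_j", "p_j": "p_i"})
    for direction, panel in (("i_given_j", merged), ("j_given_i", swapped)):
        table = _cfdr.monotonize(_cfdr.build_lookup_table(panel, pi_grid, pj_grid))
        paths[f"table_{direction}"] = outdir / f"lookup_{direction}.tsv"
        table.write(paths[f"table_{direction}"])

    for column, name in (("cfdr_i_given_j", "conditional_manhattan"),
                         ("ccfdr", "conjunction_manhattan")):
        frame = _manhattan_frame(results, column)
        paths[name] = outdir / f"{name}.tsv"
        frame.to_csv(paths[name], sep="\t", index=False, float_format="%.4F")

    loci_kwargs = dict(alpha=config.alpha, window_kb=config.clump_window_kb,
                       ld=_loci.LdTable.read(config.ld_path) if config.ld_path else None,
                       r2_clump=config.r2_clump)
    loci_principal = _loci.clump(results, "cfdr_i_given_j", **loci_kwargs)
    loci_conditioning = _loci.clump(results, "cfdr_j_given_i", **loci_kwargs)
    loci_conjunction = _loci.clump(results, "ccfdr", **loci_kwargs)
    for name, loci in (("loci_principal", loci_principal),
                       ("loci_conditioning", loci_conditioning),
                       ("loci_conjunction", loci_conjunction)):
        paths[name] = outdir / f"{name}.tsv"
        _loci.write_loci(loci, paths[name])
        counts[f"n_{name}"] = len(loci)
    for fieldname in ("cfdr_i_given_j", "cfdr_j_given_i", "ccfdr"):
        counts[f"n_sig_{fieldname}"] = len(_cfdr.significant_set(results, fieldname, config.alpha))

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "alpha": config.alpha,
        "counts": counts,
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    logger.info("discovery complete: %s", counts)
    return DiscoveryBundle(
        merged=merged, results=results,
        loci_principal=loci_principal, loci_conditioning=loci_conditioning,
        loci_conjunction=loci_conjunction, conditioning_stats=trait2,
        truth=truth, counts=counts, paths=paths,
    )


def run_replication(config: RunConfig, bundle: DiscoveryBundle) -> dict:
    """Replication pass: re-run cFDR with the replication principal set.

    In file mode the replication dataset replaces the principal trait;
    in synthetic mode an independent draw with the discovery run's
    truth labels stands in for it.  Discovery loci are then checked
    with the LD-proxy rule.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed + 1)
        rep_principal, _, _ = _sim.generate_pair(gen, labels=bundle.truth)
    elif config.replication_path is not None:
        rep_principal = _ss.read_sumstats(config.replication_path, config.replication_dialect)
    else:
        raise InputError("no replication dataset configured")

    shared = set(rep_principal["snp_id"]) & set(bundle.merged["snp_id"])
    if len(shared) < config.min_overlap:
        logger.warning(
            "replication id overlap is only %d SNPs (< %d)", len(shared), config.min_overlap
        )
    rep_merged = _ss.merge_on_snp(rep_principal, bundle.conditioning_stats)
    rep_results = _cfdr.assign_cfdr(rep_merged)

    ld = _loci.LdTable.read(config.ld_path) if config.ld_path else None
    reports = {}
    for name, loci, fieldname in (
        ("principal", bundle.loci_principal, "cfdr_i_given_j"),
        ("conjunction", bundle.loci_conjunction, "ccfdr"),
    ):
        status = _loci.replication_check(
            loci, rep_results, field_name=fieldname, alpha=config.alpha,
            ld=ld, r2_rep=config.r2_replication,
        )
        path = outdir / f"replication_{name}.tsv"
        out = status.copy()
        out["statistic"] = out["statistic"].map(lambda v: f"{v:.3E}")
        out.to_csv(path, sep="\t", index=False, float_format="%.4F")
        reports[name] = status

    summary = {
        "n_replication_snps": len(rep_merged),
        **{
            f"n_replicated_{name}": int(status["replicated"].sum())
            for name, status in reports.items()
        },
        **{f"n_loci_{name}": len(status) for name, status in reports.items()},
    }
    with open(outdir / "replication_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("replication complete: %s", summary)
    return {"results": rep_results, "reports": reports, "summary": summary}
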
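"""Locus clumping and replication cross-checking.

Significant SNPs are reduced to independent loci by greedy clumping:
the most significant unassigned SNP becomes a lead and absorbs every
unassigned significant SNP within a distance window on the same
chromosome (optionally also requiring linkage-disequilibrium r^2 above
a threshold when an LD table is supplied).  A discovery locus counts as
replicated when its lead — or a proxy SNP in high LD with the lead
(r^2 strictly greater than 0.6 by default) — passes the significance
level in an independent replication analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sumstats import chrom_sort_key

logger = logging.getLogger(__name__)

#: LD proxy threshold for replication: r^2 must be strictly greater.
DEFAULT_R2_REPLICATION = 0.6


class LdTable:
    """Symmetric pairwise r^2 lookup between SNP identifiers."""

    def __init__(self, pairs: pd.DataFrame):
        required = {"snp_a", "snp_b", "r2"}
        if not required.issubset(pairs.columns):
            raise ConfigError("LD table needs columns snp_a, snp_b, r2")
        r2 = pairs["r2"].to_numpy(dtype=float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ConfigError("r2 values must lie in [0, 1]")
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, v in zip(pairs["snp_a"], pairs["snp_b"], r2):
            self._r2[(str(a), str(b))] = v
            self._r2[(str(b), str(a))] = v

    @classmethod
    def read(cls, path: str | Path) -> "LdTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str}))

    def r2(self, a: str, b: str) -> float:
        """r^2 of a pair; 1 for a SNP with itself, 0 when unknown."""
        if a == b:
            return 1.0
        return self._r2.get((a, b), 0.0)

    def partners(self, snp: str) -> list[tuple[str, float]]:
        return [(b, v) for (a, b), v in self._r2.items() if a == snp]


@dataclass
class Locus:
    """One independent locus: its lead SNP and the SNPs clumped under it."""

    lead_snp: str
    chrom: str
    pos: int
    statistic: float
    member_snps: list[str] = field(default_factory=list)


def clump(
    results: pd.DataFrame,
    field_name: str = "ccfdr",
    alpha: float = 0.05,
    window_kb: float = 1000.0,
    ld: LdTable | None = None,
    r2_clump: float | None = None,
) -> list[Locus]:
    """Greedy reduction of significant SNPs to independent loci.

    Ties on the statistic break by (chromosome, position) so the
    partition is deterministic.  Every significant SNP ends up in
    exactly one locus.  With an LD table, a SNP joins a lead only if it
    is both within the window and at r^2 >= ``r2_clump`` with the lead.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    if field_name not in results.columns:
        raise ConfigError(f"no column {field_name!r} in results")
    sig = results[results[field_name].to_numpy(dtype=float) < alpha].copy()
    if sig.empty:
        return []
    sig["_ckey"] = chrom_sort_key(sig["chrom"])
    sig = sig.sort_values([field_name, "_ckey", "pos", "snp_id"], kind="mergesort")

    ids = sig["snp_id"].to_numpy()
    chroms = sig["chrom"].astype(str).to_numpy()
    pos = sig["pos"].to_numpy(dtype=np.int64)
    stat = sig[field_name].to_numpy(dtype=float)
    window = int(window_kb * 1000)

    assigned = np.zeros(len(sig), dtype=bool)
    loci: list[Locus] = []
    for k in range(len(sig)):
        if assigned[k]:
            continue
        near = (
            ~assigned
            & (chroms == chroms[k])
            & (np.abs(pos - pos[k]) <= window)
        )
        if ld is not None and r2_clump is not None:
            in_ld = np.array([ld.r2(ids[k], other) >= r2_clump for other in ids])
            near &= in_ld
        near[k] = True
        assigned |= near
        members = list(ids[near])
        loci.append(
            Locus(
                lead_snp=str(ids[k]),
                chrom=str(chroms[k]),
                pos=int(pos[k]),
                statistic=float(stat[k]),
                member_snps=members,
            )
        )
    return loci


def replication_check(
    discovery_loci: list[Locus],
    replication_results: pd.DataFrame,
    field_name: str = "ccfdr",
    alpha: float = 0.05,
    ld: LdTable | None = None,
    r2_rep: float = DEFAULT_R2_REPLICATION,
) -> pd.DataFrame:
    """Replication status of each discovery locus.

    A locus replicates when its lead passes ``alpha`` in the
    replication results, or when any replication-significant SNP on the
    same chromosome has r^2 strictly greater than ``r2_rep`` with the
    lead.  Without an LD table only exact-id matching is possible and
    the output flags that.

    Returns a frame with one row per locus: lead, chrom, pos,
    statistic, n_members, replicated, proxy_id, proxy_r2,
    ld_available.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    if ld is None:
        logger.warning("no LD table supplied; replication uses exact id matching only")
    rep = replication_results
    rep_sig = rep[rep[field_name].to_numpy(dtype=float) < alpha]
    sig_by_id = dict(zip(rep_sig["snp_id"].astype(str), rep_sig[field_name]))
    chrom_by_id = dict(zip(rep_sig["snp_id"].astype(str), rep_sig["chrom"].astype(str)))

    rows = []
    for locus in discovery_loci:
        replicated = False
        proxy_id, proxy_r2 = "", np.nan
        if locus.lead_snp in sig_by_id:
            replicated = True
            proxy_id, proxy_r2 = locus.lead_snp, 1.0
        elif ld is not None:
            best = None
            for cand, stat in sig_by_id.items():
                if chrom_by_id[cand] != locus.chrom:
                    continue  # cross-chromosome proxies are never accepted
                r2 = ld.r2(locus.lead_snp, cand)
                if r2 > r2_rep and (best is None or r2 > best[1]):
                    best = (cand, r2)
            if best is not None:
                replicated = True
                proxy_id, proxy_r2 = best
        rows.append(
            {
                "lead": locus.lead_snp,
                "chrom": locus.chrom,
                "pos": locus.pos,
                "statistic": locus.statistic,
                "n_members": len(locus.member_snps),
                "replicated": replicated,
                "proxy_id": proxy_id,
                "proxy_r2": proxy_r2,
                "ld_available": ld is not None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lead", "chrom", "pos", "statistic", "n_members",
            "replicated", "proxy_id", "proxy_r2", "ld_available",
        ],
    )


def union_clump(
    results_list: list[pd.DataFrame],
    field_name: str = "cfdr_i_given_j",
    alpha: float = 0.05,
    window_kb: float = 1000.0,
    ld: LdTable | None = None,
    r2_clump: float | None = None,
) -> list[Locus]:
    """Independent loci over the union of several conditioning runs.

    When the same principal trait is conditioned on more than one
    second trait, per-SNP results are pooled by keeping each SNP's
    smallest statistic across runs, then clumped once — the bookkeeping
    that turns per-conditioning hit lists into one independent count.
    """
    pooled = pd.concat(results_list, ignore_index=True)
    pooled = pooled.sort_values(field_name, kind="mergesort").drop_duplicates("snp_id", keep="first")
    return clump(pooled, field_name=field_name, alpha=alpha, window_kb=window_kb,
                 ld=ld, r2_clump=r2_clump)


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lead": l.lead_snp,
                "chrom": l.chrom,
                "pos": l.pos,
                "statistic": l.statistic,
                "n_members": len(l.member_snps),
                "members": ",".join(l.member_snps),
            }
            for l in loci
        ],
        columns=["lead", "chrom", "pos", "statistic", "n_members", "members"],
    )


def write_loci(loci: list[Locus], path: str | Path) -> None:
    df = loci_to_frame(loci)
    df["statistic"] = df["statistic"].map(lambda v: f"{v:.3E}")
    df.to_csv(path, sep="\t", index=False)
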
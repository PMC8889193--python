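"""Site filters and per-gene modification-fraction statistics.

The central quantity is the modification fraction of a region,
``N_modCG / N_totalCG``: the number of modified CGs over the total number
of CG dinucleotides in the region.  "Modified" is binary — for TOP-seq
style single-CG data a site counts as modified when it survives the
combined-replicate coverage filter; for WGBS a CG counts when its
methylation level exceeds 50% (strictly) at >= 5 reads.

Deciles/quartiles and the low/high decile flags are computed on non-zero
values only, with boundary ties assigned to the lower group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from oximap.core import (
    CGSite,
    ConfigError,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    ModCall,
    Scaffold,
    TEFeature,
    WGBSCall,
)

TOPSEQ_MIN_COV = 2
TOPSEQ_MIN_SCAFFOLD = 100_000
WGBS_MIN_READS = 5
WGBS_METH_THRESHOLD = 0.5
EXPRESSED_TPM = 0.05


@dataclass
class GeneModStats:
    """Per-gene modification statistics (one row of the gene table)."""

    gene_id: str
    n_cg: int
    n_mod: dict[str, int] = field(default_factory=dict)
    fraction: dict[str, float] = field(default_factory=dict)
    cov_value: dict[str, float] = field(default_factory=dict)
    tpm: float = float("nan")
    expressed: bool = False
    te_context: str = "clean"
    in_cluster: bool = False


def combine_replicates(calls: Iterable[ModCall]) -> dict[CGSite, int]:
    """Sum coverages of technical replicates per CG site."""
    combined: dict[CGSite, int] = {}
    for c in calls:
        combined[c.site] = combined.get(c.site, 0) + c.coverage
    return combined


def combined_modcalls(calls: Sequence[ModCall]) -> list[ModCall]:
    """One call per site with replicate coverages summed (sorted)."""
    if not calls:
        return []
    mod = calls[0].mod
    combined = combine_replicates(calls)
    return [
        ModCall(site, mod, cov, sample_id="combined")
        for site, cov in sorted(combined.items())
    ]


def filter_topseq_calls(
    calls: Sequence[ModCall],
    scaffolds: Sequence[Scaffold],
    min_cov: int = TOPSEQ_MIN_COV,
    min_scaffold: int = TOPSEQ_MIN_SCAFFOLD,
) -> set[CGSite]:
    """Modified-CG set for single-CG (TOP-seq style) data.

    Technical replicates are combined by summing coverage per site; a site
    is retained when the combined coverage is >= ``min_cov`` and it lies on
    a scaffold longer than ``min_scaffold`` bp.
    """
    long_enough = {s.id for s in scaffolds if s.length > min_scaffold}
    combined = combine_replicates(calls)
    return {
        site
        for site, cov in combined.items()
        if cov >= min_cov and site.scaffold in long_enough
    }


def filter_wgbs_sites(
    calls: Sequence[WGBSCall],
    min_reads: int = WGBS_MIN_READS,
    meth_threshold: float = WGBS_METH_THRESHOLD,
) -> tuple[dict[CGSite, float], set[CGSite]]:
    """Per-CG methylation levels and the modified-CG set from WGBS counts.

    Sites with < ``min_reads`` total reads are dropped; the modified set
    contains sites with level strictly above ``meth_threshold``.
    """
    levels: dict[CGSite, float] = {}
    modified: set[CGSite] = set()
    for c in calls:
        if c.total < min_reads:
            continue
        levels[c.site] = c.level
        if c.level > meth_threshold:
            modified.add(c.site)
    return levels, modified


def _positions_by_scaffold(sites: Iterable[CGSite]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for s in sites:
        by.setdefault(s.scaffold, []).append(s.pos)
    return {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in by.items()}


def region_fraction(
    region: GenomicInterval,
    all_cg: set[CGSite] | Mapping[str, np.ndarray],
    mod_cg: set[CGSite] | Mapping[str, np.ndarray],
) -> float:
    """Modification fraction of a region: modified CGs / total CGs inside.

    Returns NaN (undefined) when the region contains no CG; such regions
    are excluded downstream.
    """
    total = _count_in(all_cg, region)
    if total == 0:
        return float("nan")
    return _count_in(mod_cg, region) / total


def _count_in(sites, region: GenomicInterval) -> int:
    if isinstance(sites, Mapping):
        pos = sites.get(region.scaffold)
        if pos is None:
            return 0
        return int(
            np.searchsorted(pos, region.end, "left") - np.searchsorted(pos, region.start, "left")
        )
    return sum(
        1 for s in sites if s.scaffold == region.scaffold and region.start <= s.pos < region.end
    )


def region_cov_value(region: GenomicInterval, calls: Sequence[ModCall]) -> float:
    """Mean per-CG coverage over the region's modified CGs (0 when none).

    A complementary, semi-quantitative measure alongside the binary
    fraction: regions with few but deeply covered modified sites score
    high here while their fraction stays low.
    """
    covs = [
        c.coverage
        for c in calls
        if c.site.scaffold == region.scaffold and region.start <= c.site.pos < region.end
    ]
    return float(np.mean(covs)) if covs else 0.0


def _mean_cov(by_scaf: Mapping[str, tuple[np.ndarray, np.ndarray]], region: GenomicInterval) -> float:
    arr = by_scaf.get(region.scaffold)
    if arr is None:
        return 0.0
    pos, cov = arr
    lo = np.searchsorted(pos, region.start, "left")
    hi = np.searchsorted(pos, region.end, "left")
    return float(cov[lo:hi].mean()) if hi > lo else 0.0


def stratify(values: pd.Series | Mapping[str, float], k: int) -> pd.Series:
    """Assign genes to ``k`` equal-probability groups (1..k) by quantiles.

    Zeros are excluded before the quantile edges are computed and receive
    no group (pd.NA).  Edges are empirical order statistics (inverted CDF),
    and a value equal to an edge falls in the lower group, so each group's
    occupancy differs from n/k by at most one for distinct values and ties
    always share a group.
    """
    s = pd.Series(values, dtype=float)
    nz = s[(s != 0) & s.notna()]
    if len(nz) < k:
        raise ConfigError(f"need >= {k} non-zero values to form {k} groups, have {len(nz)}")
    edges = np.quantile(nz.to_numpy(), np.arange(1, k) / k, method="inverted_cdf")
    groups = pd.Series(pd.NA, index=s.index, dtype="Int64")
    groups[nz.index] = 1 + np.searchsorted(edges, nz.to_numpy(), side="left")
    return groups


def low_high_flags(values: pd.Series | Mapping[str, float]) -> pd.Series:
    """Flag genes in the first ('low') or last ('high') decile of non-zero
    values; everything else (including zeros) is 'neither'."""
    groups = stratify(values, 10)
    flags = pd.Series("neither", index=groups.index, dtype=object)
    flags[groups == 1] = "low"
    flags[groups == 10] = "high"
    return flags


def gene_mod_stats(
    genes: Sequence[GeneModel],
    all_cg: Iterable[CGSite],
    mod_sets: Mapping[str, set[CGSite]],
    calls: Mapping[str, Sequence[ModCall]] | None = None,
    expression: Sequence[ExpressionRecord] | None = None,
    tes: Sequence[TEFeature] | None = None,
    clusters: Sequence | None = None,
    scaffolds: Sequence[Scaffold] | None = None,
    region: str = "body",
    topseq_filter_active: bool = False,
) -> pd.DataFrame:
    """Assemble the per-gene statistics table.

    One row per gene: total CGs, modified-CG counts and fractions per
    modification, optional coverage values, TPM and expressed flag,
    TE-context label and cluster membership.  ``region`` selects the gene
    body (default) or the 1-kb upstream promoter proxy.  When the TOP-seq
    scaffold filter is active, genes on scaffolds <= 100 kb are excluded
    for consistency with the site filter.
    """
    from oximap.clusters import assign_cluster_membership
    from oximap.expression import classify_te_context, expressed_flag

    lengths = {s.id: s.length for s in scaffolds} if scaffolds else {}
    if topseq_filter_active:
        if not scaffolds:
            raise ConfigError("scaffolds required when the TOP-seq filter is active")
        genes = [g for g in genes if lengths[g.body.scaffold] > TOPSEQ_MIN_SCAFFOLD]

    all_pos = _positions_by_scaffold(all_cg)
    mod_pos = {m: _positions_by_scaffold(s) for m, s in mod_sets.items()}
    tpm_by_gene = {r.gene_id: r.tpm for r in expression or []}

    # sorted (position, coverage) arrays per scaffold for fast mean coverage
    cov_arrays: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for m, call_list in (calls or {}).items():
        by: dict[str, list[tuple[int, int]]] = {}
        for c in call_list:
            by.setdefault(c.site.scaffold, []).append((c.site.pos, c.coverage))
        cov_arrays[m] = {}
        for scaf, pairs in by.items():
            pairs.sort()
            arr = np.asarray(pairs, dtype=np.int64)
            cov_arrays[m][scaf] = (arr[:, 0], arr[:, 1])

    regions: list[GenomicInterval | None] = []
    for g in genes:
        if region == "body":
            regions.append(g.body)
        elif region == "upstream":
            regions.append(g.upstream_interval(lengths.get(g.body.scaffold)))
        else:
            raise ConfigError(f"unknown region kind {region!r}")

    if tes is not None:
        contexts = [classify_te_context(g, tes) for g in genes]
    else:
        contexts = [("clean", "TE-")] * len(genes)
    if clusters:
        in_cluster = assign_cluster_membership([g.body for g in genes], clusters)
    else:
        in_cluster = np.zeros(len(genes), dtype=bool)

    rows = []
    for i, (g, reg) in enumerate(zip(genes, regions)):
        rec: dict = {"gene_id": g.gene_id}
        n_cg = _count_in(all_pos, reg) if reg is not None else 0
        rec["n_cg"] = n_cg
        for m in mod_sets:
            n_mod = _count_in(mod_pos[m], reg) if reg is not None else 0
            rec[f"n_{m}"] = n_mod
            rec[f"fraction_{m}"] = n_mod / n_cg if n_cg else float("nan")
            if calls and m in calls:
                rec[f"cov_{m}"] = (
                    _mean_cov(cov_arrays[m], reg) if reg is not None else 0.0
                )
        tpm = tpm_by_gene.get(g.gene_id, float("nan"))
        rec["tpm"] = tpm
        rec["expressed"] = bool(expressed_flag(tpm)) if tpm == tpm else False
        rec["te_context"] = contexts[i][0]
        rec["te_coarse"] = "in_cluster" if in_cluster[i] else contexts[i][1]
        rec["in_cluster"] = bool(in_cluster[i])
        rows.append(rec)
    return pd.DataFrame(rows)
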
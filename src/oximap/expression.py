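"""Gene--TE context classification and modification--expression association.

Genes are classified by TE proximity (overlap / upstream / downstream /
up+downstream within 1 kb / clean), compared across groups with
Kruskal--Wallis (fractions) or one-way ANOVA on log2(TPM+1) (expression),
cross-tabulated by 5mC and oxi-mC fraction strata, and reduced to a
unique-gene set through a protein-similarity filter.

A gene is "expressed" when TPM > 0.05 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from oximap.core import (
    ConfigError,
    GeneModel,
    TEFeature,
    ValidationError,
)
from oximap.fractions import EXPRESSED_TPM

TE_DISTANCE = 1000

FINE_LABELS = ("clean", "upstream", "downstream", "up/downstream", "overlap")


def classify_te_context(
    gene: GeneModel, tes: Sequence[TEFeature], distance: int = TE_DISTANCE
) -> tuple[str, str]:
    """Classify a gene by TE proximity; returns (fine, coarse) labels.

    overlap: a TE intersects the gene body; otherwise upstream/downstream
    are decided strand-aware from the transcription direction for TEs with
    a gap strictly below ``distance``; both sides present gives
    "up/downstream"; none gives "clean".  Coarse label is "TE+" iff any TE
    overlaps or lies within the distance, else "TE-".
    """
    body = gene.body
    left = False  # TE proximal on the lower-coordinate side
    right = False
    for te in tes:
        loc = te.location
        if loc.scaffold != body.scaffold:
            continue
        if loc.start < body.end and body.start < loc.end:
            return "overlap", "TE+"
        if loc.end <= body.start and body.start - loc.end < distance:
            left = True
        elif loc.start >= body.end and loc.start - body.end < distance:
            right = True
    if gene.strand == "+":
        up, down = left, right
    else:
        up, down = right, left
    if up and down:
        return "up/downstream", "TE+"
    if up:
        return "upstream", "TE+"
    if down:
        return "downstream", "TE+"
    return "clean", "TE-"


def expressed_flag(tpm: float) -> bool:
    """True iff the gene is expressed: TPM strictly above 0.05."""
    if tpm < 0:
        raise ValidationError(f"negative TPM {tpm}")
    return tpm > EXPRESSED_TPM


def log2_tpm(tpm) -> np.ndarray:
    return np.log2(np.asarray(tpm, dtype=float) + 1.0)


def group_compare(groups: Mapping[str, Sequence[float]], kind: str) -> tuple[float, float]:
    """Omnibus test across >= 2 groups; returns (statistic, p).

    ``kind='fraction'`` uses Kruskal--Wallis on raw values;
    ``kind='expression'`` uses one-way ANOVA on log2(TPM+1).
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    arrays = []
    for label, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ConfigError(f"group {label!r} has < 2 observations")
        arrays.append(v)
    if kind == "fraction":
        res = stats.kruskal(*arrays)
    elif kind == "expression":
        res = stats.f_oneway(*(log2_tpm(a) for a in arrays))
        # between-group variance of exactly zero yields F = -0.0 and a NaN p
        if not np.isfinite(res.pvalue) and res.statistic <= 0:
            return 0.0, 1.0
    else:
        raise ConfigError(f"unknown comparison kind {kind!r}")
    return float(res.statistic), float(res.pvalue)


def pairwise_compare(a: Sequence[float], b: Sequence[float], kind: str) -> tuple[float, float]:
    """Two-group contrast: Wilcoxon rank-sum for fractions, t-test on
    log2(TPM+1) for expression; returns (statistic, p)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs >= 2 observations")
    if kind == "fraction":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif kind == "expression":
        res = stats.ttest_ind(log2_tpm(a), log2_tpm(b))
    else:
        raise ConfigError(f"unknown comparison kind {kind!r}")
    return float(res.statistic), float(res.pvalue)


def expression_by_modification(
    genes: pd.DataFrame,
    mc_bins: Sequence[float] = (0.0, 0.1, 0.5, 1.0),
    oxi_bins: Sequence[float] = (0.1, 0.3, 1.0),
    mc_col: str = "fraction_5mC",
    oxi_col: str = "fraction_5hmC",
    tpm_col: str = "tpm",
    cluster_col: str = "in_cluster",
) -> dict[str, pd.DataFrame]:
    """Expression stratified by 5mC fraction group and oxi-mC fraction group.

    Genes are cross-tabulated into 5mC strata (right-closed bins over
    ``mc_bins`` edges) by oxi-mC groups, with a dedicated "none" group for
    genes with zero oxi-mC fraction, separately inside and outside TE
    clusters.  Returns ``cells`` (n, mean and median log2(TPM+1) per cell)
    and ``trends`` (slope of log2(TPM+1) on the oxi-mC fraction per 5mC
    stratum and cluster status, with the regression p-value).
    """
    df = genes[[mc_col, oxi_col, tpm_col, cluster_col]].copy()
    df = df[np.isfinite(df[mc_col]) & np.isfinite(df[oxi_col]) & np.isfinite(df[tpm_col])]
    if df.empty:
        raise ConfigError("no genes with defined fractions and TPM")
    df["expr"] = log2_tpm(df[tpm_col])

    mc_edges = list(mc_bins)
    df["mc_group"] = pd.cut(df[mc_col], mc_edges, include_lowest=True, right=True).astype(str)

    oxi_edges = [0.0, *oxi_bins]
    oxi_lab = pd.cut(df[oxi_col], oxi_edges, include_lowest=True, right=True).astype(str)
    oxi_lab[df[oxi_col] == 0] = "none"
    df["oxi_group"] = oxi_lab

    cells = (
        df.groupby([cluster_col, "mc_group", "oxi_group"], observed=True)["expr"]
        .agg(n="size", mean_expr="mean", median_expr="median")
        .reset_index()
    )

    trends = []
    for (clu, mcg), sub in df.groupby([cluster_col, "mc_group"], observed=True):
        if len(sub) < 3 or sub[oxi_col].nunique() < 2:
            slope, p = float("nan"), float("nan")
        else:
            fit = stats.linregress(sub[oxi_col], sub["expr"])
            slope, p = float(fit.slope), float(fit.pvalue)
        trends.append(
            dict(in_cluster=clu, mc_group=mcg, n=len(sub), slope=slope, p=p)
        )
    return {"cells": cells, "trends": pd.DataFrame(trends)}


@dataclass(frozen=True)
class ProteinAlignmentRecord:
    """One pairwise protein alignment hit (blastp-style, percentages)."""

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    n_unmatched: float
    c_unmatched: float

    def __post_init__(self) -> None:
        for name in ("identity", "coverage", "n_unmatched", "c_unmatched"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValidationError(f"{name} must be a percentage in [0,100], got {v}")


SIMILAR_IDENTITY = 95.0
SIMILAR_COVERAGE = 90.0
SIMILAR_END_UNMATCHED = 5.0


def is_similar(rec: ProteinAlignmentRecord) -> bool:
    """Does one alignment hit mark the pair as non-unique?"""
    return (
        rec.identity >= SIMILAR_IDENTITY
        and rec.coverage >= SIMILAR_COVERAGE
        and rec.n_unmatched <= SIMILAR_END_UNMATCHED
        and rec.c_unmatched <= SIMILAR_END_UNMATCHED
    )


def unique_gene_filter(
    records: Sequence[ProteinAlignmentRecord], all_genes: Sequence[str]
) -> set[str]:
    """Collapse protein-similar genes to one representative each.

    Pairs passing all similarity thresholds (identity >= 95%, coverage >=
    90%, <= 5% unmatched at both protein ends) are joined into connected
    components (similarity made transitive by union-find); the
    lexicographically smallest gene id represents each component.  Genes
    with no similar partner are retained.  Idempotent and order-invariant.
    """
    gene_set = set(all_genes)
    parent: dict[str, str] = {g: g for g in gene_set}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rec in records:
        for gid in (rec.query_id, rec.subject_id):
            if gid not in gene_set:
                raise ValidationError(f"alignment references unknown gene id {gid!r}")
        if rec.query_id == rec.subject_id:
            continue
        if is_similar(rec):
            ra, rb = find(rec.query_id), find(rec.subject_id)
            if ra != rb:
                # attach the larger root under the smaller for determinism
                if ra < rb:
                    parent[rb] = ra
                else:
                    parent[ra] = rb

    components: dict[str, str] = {}
    for g in gene_set:
        root = find(g)
        if root not in components or g < components[root]:
            components[root] = g
    return set(components.values())
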
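"""Genomic-feature enrichment of modified units via Fisher's exact test.

Units are either single CGs or 200-bp windows.  For each feature class a
2x2 contingency table is formed — modified/unmodified units inside/outside
the feature's interval union — and Fisher's exact test gives a two-sided
p-value; the effect size is the log2 sample odds ratio.  No multiple-
testing correction is applied by default (significance is raw p < 0.05,
as in the figure convention); Benjamini–Hochberg adjustment is available
behind a flag.

Feature membership is non-exclusive: a CG in an exonic TE counts for both
the exon and the TE rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from oximap.core import (
    CGSite,
    ConfigError,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    Scaffold,
    TEFeature,
    ValidationError,
)

ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyResult:
    """Fisher's exact test on a 2x2 modified-by-feature table.

    Cells: a = modified & in-feature, b = modified & outside,
    c = unmodified & in-feature, d = unmodified & outside.
    """

    feature: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    log2_or: float
    p: float
    significant: bool

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _membership(units, feature_set: IntervalSet) -> np.ndarray:
    """Boolean per unit: CG position inside / window overlapping the union."""
    units = list(units)
    if not units:
        return np.zeros(0, dtype=bool)
    out = np.zeros(len(units), dtype=bool)
    if isinstance(units[0], CGSite):
        by_scaf: dict[str, list[int]] = {}
        for i, u in enumerate(units):
            by_scaf.setdefault(u.scaffold, []).append(i)
        for scaf, idx in by_scaf.items():
            pos = np.array([units[i].pos for i in idx])
            out[np.asarray(idx)] = feature_set.contains(scaf, pos)
    else:
        out = feature_set.overlaps_intervals(units)
    return out


def build_contingency(
    units: Sequence,
    modified: set,
    feature: IntervalSet | Sequence[GenomicInterval],
) -> tuple[int, int, int, int]:
    """2x2 counts of units by modification state and feature membership.

    ``units`` is a sequence of CG sites or of window intervals; ``modified``
    must be a subset of it.  A unit is "in feature" when it overlaps the
    feature's interval union (CG: position inside; window: >= 1 bp).
    """
    units = list(units)
    unit_set = set(units)
    if not modified <= unit_set:
        raise ValidationError("modified units are not a subset of all units")
    fs = feature if isinstance(feature, IntervalSet) else IntervalSet(feature)
    inside = _membership(units, fs)
    is_mod = np.array([u in modified for u in units], dtype=bool)
    a = int(np.sum(is_mod & inside))
    b = int(np.sum(is_mod & ~inside))
    c = int(np.sum(~is_mod & inside))
    d = int(np.sum(~is_mod & ~inside))
    return a, b, c, d


def fisher_or(table: tuple[int, int, int, int], feature: str = "", alpha: float = ALPHA) -> ContingencyResult:
    """Fisher's exact test (two-sided) and sample odds ratio for a table.

    The odds ratio is (a*d)/(b*c); when any cell is zero the
    Haldane–Anscombe correction (+0.5 to every cell) is applied so the
    log2 odds ratio stays finite.  The p-value always uses the raw counts.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValidationError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise ValidationError("all-zero contingency table")
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return ContingencyResult(feature, a, b, c, d, orr, float(np.log2(orr)), p, p < alpha)


def enrichment_profile(
    units: Sequence,
    modified_sets: Mapping[str, set],
    features: Mapping[str, Sequence[GenomicInterval] | IntervalSet],
    alpha: float = ALPHA,
    fdr_correct: bool = False,
) -> pd.DataFrame:
    """Long-format enrichment table: one row per (modification, feature).

    Rows whose table is degenerate (empty feature, empty modification set,
    or a feature covering every unit) carry ``defined=False`` with NaN
    statistics.  With ``fdr_correct`` the significance flag uses
    Benjamini–Hochberg-adjusted p-values at the same alpha.
    """
    rows = []
    for mod, modified in modified_sets.items():
        for label, feat in features.items():
            fs = feat if isinstance(feat, IntervalSet) else IntervalSet(feat)
            a, b, c, d = build_contingency(units, modified, fs)
            degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
            if degenerate:
                rows.append(
                    dict(
                        modification=mod, feature=label, a=a, b=b, c=c, d=d,
                        odds_ratio=np.nan, log2_or=np.nan, p=np.nan,
                        significant=False, defined=False,
                    )
                )
                continue
            r = fisher_or((a, b, c, d), feature=label, alpha=alpha)
            rows.append(
                dict(
                    modification=mod, feature=label, a=a, b=b, c=c, d=d,
                    odds_ratio=r.odds_ratio, log2_or=r.log2_or, p=r.p,
                    significant=r.significant, defined=True,
                )
            )
    df = pd.DataFrame(rows)
    if fdr_correct and df["defined"].any():
        from scipy.stats import false_discovery_control

        mask = df["defined"].to_numpy()
        adj = false_discovery_control(df.loc[mask, "p"].to_numpy(), method="bh")
        df.loc[mask, "p_adj"] = adj
        df.loc[mask, "significant"] = adj < alpha
    return df


def standard_feature_map(
    genes: Sequence[GeneModel],
    tes: Sequence[TEFeature],
    scaffolds: Sequence[Scaffold],
    clusters: Sequence = (),
    repeats_excl_te: Sequence[GenomicInterval] = (),
    tet_gene_ids: set[str] | frozenset[str] = frozenset(),
) -> dict[str, IntervalSet]:
    """Derive the standard feature classes from annotations.

    exon, intron, UTR5, UTR3, upstream (1 kb promoter proxy), TE split into
    gene-associated and intergenic by gene-body overlap, repeats excluding
    TEs (user-supplied), intergenic (no gene body), TE clusters (final
    intervals), and an optional user-supplied TET-gene list.
    """
    lengths = {s.id: s.length for s in scaffolds}
    gene_union = IntervalSet(g.body for g in genes)

    te_ivs = [t.location for t in tes]
    te_overlaps_gene = gene_union.overlaps_intervals(te_ivs) if te_ivs else np.zeros(0, bool)
    upstream = [
        iv for g in genes if (iv := g.upstream_interval(lengths.get(g.body.scaffold))) is not None
    ]

    # intergenic = complement of gene bodies over the scaffolds
    intergenic: list[GenomicInterval] = []
    merged = gene_union
    for s in scaffolds:
        prev = 0
        for iv in (i for i in merged.intervals() if i.scaffold == s.id):
            if iv.start > prev:
                intergenic.append(GenomicInterval(s.id, prev, iv.start))
            prev = iv.end
        if prev < s.length:
            intergenic.append(GenomicInterval(s.id, prev, s.length))

    features: dict[str, IntervalSet] = {
        "exon": IntervalSet(e for g in genes for e in g.exons),
        "intron": IntervalSet(i for g in genes for i in g.introns()),
        "UTR5": IntervalSet(u for g in genes for u in g.utr5),
        "UTR3": IntervalSet(u for g in genes for u in g.utr3),
        "upstream": IntervalSet(upstream),
        "TE_gene_associated": IntervalSet(
            iv for iv, hit in zip(te_ivs, te_overlaps_gene) if hit
        ),
        "TE_intergenic": IntervalSet(
            iv for iv, hit in zip(te_ivs, te_overlaps_gene) if not hit
        ),
        "TE": IntervalSet(te_ivs),
        "intergenic": IntervalSet(intergenic),
    }
    if repeats_excl_te:
        features["repeats_excl_TE"] = IntervalSet(repeats_excl_te)
    if clusters:
        features["TE_cluster"] = IntervalSet(c.final for c in clusters)
    if tet_gene_ids:
        features["TET_genes"] = IntervalSet(
            g.body for g in genes if g.gene_id in tet_gene_ids
        )
    return features
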
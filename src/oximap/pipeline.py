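"""End-to-end pipeline on a synthetic genome.

Chains every analysis stage on generated data: Seal window signal with
background subtraction and bin-overlap Jaccard, TE-cluster detection with
genome-level summaries, single-CG filtering, per-gene fraction statistics,
feature enrichment, and the modification--expression association analyses.
Writes deterministic text outputs plus a JSON of headline numbers; a fixed
seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

from oximap import io as oio
from oximap.clusters import assign_cluster_membership, cluster_summary, detect_te_clusters
from oximap.enrichment import enrichment_profile, standard_feature_map
from oximap.expression import expression_by_modification, pairwise_compare
from oximap.fractions import (
    combined_modcalls,
    filter_topseq_calls,
    filter_wgbs_sites,
    gene_mod_stats,
)
from oximap.seal import (
    deduplicate_fragments,
    jaccard_bins,
    positive_windows,
    subtract_background,
    window_coverage,
)
from oximap.simulate import OXI_MODS, SyntheticConfig, simulate


def run_pipeline(config: SyntheticConfig | None = None, outdir: str | Path | None = None) -> dict:
    """Simulate, analyse, and (optionally) write all outputs.

    Returns the headline numbers: cluster counts and genome coverage,
    Seal bin Jaccard between the two oxi-mC maps, TE enrichment of 5hmCGs,
    and the modification--expression association statistics.
    """
    config = config if config is not None else SyntheticConfig()
    out = Path(outdir) if outdir is not None else None
    genome = simulate(config, outdir=out / "synthetic" if out else None)

    # --- Seal window signal per oxi modification --------------------------
    pos_bins: dict[str, set] = {}
    for mod in OXI_MODS:
        sample, control = genome.fragments[mod]
        s_frags = deduplicate_fragments(sample)
        c_frags = deduplicate_fragments(control)
        wins, s_cov = window_coverage(s_frags, genome.scaffolds)
        _, c_cov = window_coverage(c_frags, genome.scaffolds)
        signals = subtract_background(wins, s_cov, wins, c_cov)
        pos_bins[mod] = positive_windows(signals)
        if out:
            oio.write_bedgraph(
                out / f"seal_signal_{mod}.bedGraph",
                [w.window for w in signals],
                [w.signal for w in signals],
            )
    seal_jaccard = jaccard_bins(pos_bins["5hmC"], pos_bins["5fC"])

    # --- TE clusters ------------------------------------------------------
    clusters = detect_te_clusters(genome.tes, genome.scaffolds)
    summary = cluster_summary(clusters, genome.scaffolds)
    if out:
        with open(out / "te_clusters.bed", "w") as fh:
            for k, c in enumerate(clusters):
                fh.write(
                    f"{c.final.scaffold}\t{c.final.start}\t{c.final.end}\tcluster_{k}"
                    f"\t{c.core.start}\t{c.core.end}\t{c.n_te}\t{c.te_fraction:.4f}\n"
                )

    # --- single-CG filters and per-gene statistics ------------------------
    mod_sets = {
        mod: filter_topseq_calls(genome.modcalls[mod], genome.scaffolds)
        for mod in OXI_MODS
    }
    _, wgbs_modified = filter_wgbs_sites(genome.wgbs)
    mod_sets["5mC"] = wgbs_modified
    gene_table = gene_mod_stats(
        genome.genes,
        genome.cg_sites,
        mod_sets,
        calls={m: combined_modcalls(genome.modcalls[m]) for m in OXI_MODS},
        expression=genome.expression,
        tes=genome.tes,
        clusters=clusters,
        scaffolds=genome.scaffolds,
        topseq_filter_active=True,
    )
    if out:
        gene_table.to_csv(out / "gene_stats.tsv", sep="\t", index=False, float_format="%.6g")

    # --- enrichment across genomic features -------------------------------
    features = standard_feature_map(genome.genes, genome.tes, genome.scaffolds, clusters)
    profile = enrichment_profile(genome.cg_sites, mod_sets, features)
    if out:
        profile.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    te_row = profile[(profile.modification == "5hmC") & (profile.feature == "TE")]
    te_log2_or = float(te_row.log2_or.iloc[0]) if len(te_row) else float("nan")

    # --- modification vs expression ---------------------------------------
    df = gene_table[np.isfinite(gene_table.fraction_5hmC) & np.isfinite(gene_table.tpm)]
    oxi_frac = (df.fraction_5hmC + df.fraction_5fC) / 2
    expr = np.log2(df.tpm + 1.0)
    rho, rho_p = sps.spearmanr(oxi_frac, expr)

    in_cl = df[df.in_cluster]
    clean = df[(~df.in_cluster) & (df.te_context == "clean")]
    result = {
        "n_genes": len(gene_table),
        "n_te_clusters": summary["n_clusters"],
        "cluster_total_bp": summary["total_bp"],
        "cluster_genome_fraction": summary["genome_fraction"],
        "mean_te_per_cluster": summary["mean_te_per_cluster"],
        "seal_jaccard_5hmC_5fC": seal_jaccard,
        "te_log2_or_5hmC": te_log2_or,
        "spearman_expr_vs_oxi_fraction": float(rho),
        "spearman_p": float(rho_p),
    }
    if len(in_cl) >= 2 and len(clean) >= 2:
        _, p_frac = pairwise_compare(in_cl.fraction_5hmC, clean.fraction_5hmC, "fraction")
        _, p_expr = pairwise_compare(in_cl.tpm, clean.tpm, "expression")
        result["cluster_vs_clean_fraction_p"] = p_frac
        result["cluster_vs_clean_expression_p"] = p_expr
        result["mean_fraction_in_cluster"] = float(in_cl.fraction_5hmC.mean())
        result["mean_fraction_clean"] = float(clean.fraction_5hmC.mean())

    try:
        strat = expression_by_modification(gene_table)
        if out:
            strat["trends"].to_csv(out / "expression_trends.tsv", sep="\t", index=False, float_format="%.6g")
        result["expression_trend_slopes"] = strat["trends"]["slope"].dropna().tolist()
    except Exception:
        result["expression_trend_slopes"] = []

    if out:
        with open(out / "pipeline_stats.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
    return result
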
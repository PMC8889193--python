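"""Gene--TE context, group comparisons, stratified expression, unique genes."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_te_context
from oximap.core import ConfigError, GeneModel, GenomicInterval, TEFeature, ValidationError
from oximap.expression import (
    ProteinAlignmentRecord,
    classify_te_context,
    expressed_flag,
    expression_by_modification,
    group_compare,
    pairwise_compare,
    unique_gene_filter,
)


def gene(start, end, strand="+", gid="g"):
    return GeneModel(gid, GenomicInterval("s1", start, end, strand))


def te(start, end):
    return TEFeature(f"te{start}", GenomicInterval("s1", start, end))


class TestTeContext:
    def test_overlap(self):
        assert classify_te_context(gene(1000, 3000), [te(2500, 4000)]) == ("overlap", "TE+")

    def test_strand_aware_upstream_downstream(self):
        # TE ends 500 bp before the gene start
        tes = [te(100, 500)]
        assert classify_te_context(gene(1000, 3000, "+"), tes)[0] == "upstream"
        assert classify_te_context(gene(1000, 3000, "-"), tes)[0] == "downstream"

    def test_both_sides(self):
        tes = [te(100, 500), te(3100, 3600)]
        assert classify_te_context(gene(1000, 3000, "+"), tes) == ("up/downstream", "TE+")

    def test_exact_1kb_gap_is_clean(self):
        tes = [te(100, 1000)]  # gap to gene start 2000 is exactly 1000
        assert classify_te_context(gene(2000, 3000, "+"), tes) == ("clean", "TE-")
        closer = [te(100, 1001)]  # gap 999
        assert classify_te_context(gene(2000, 3000, "+"), closer)[0] == "upstream"

    def test_matches_nearest_te_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            gs = int(rng.integers(3000, 20_000))
            ge = gs + int(rng.integers(500, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            spans = []
            for _ in range(int(rng.integers(0, 6))):
                a = int(rng.integers(0, 25_000))
                spans.append((a, a + int(rng.integers(100, 2000))))
            got, coarse = classify_te_context(gene(gs, ge, strand), [te(a, b) for a, b in spans])
            want = brute_te_context(gs, ge, strand, spans)
            assert got == want
            assert (coarse == "TE+") == (want != "clean")


class TestExpressedFlag:
    @pytest.mark.parametrize("tpm,flag", [(0.05, False), (0.0501, True), (0.0, False)])
    def test_strict_threshold(self, tpm, flag):
        assert expressed_flag(tpm) is flag

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValidationError):
            expressed_flag(-1.0)


class TestGroupCompare:
    def test_identical_groups_null(self):
        vals = list(np.linspace(1, 10, 30))
        stat, p = group_compare({"a": vals, "b": vals, "c": vals}, "expression")
        assert p == pytest.approx(1.0)

    def test_generated_cluster_effect_detected(self, default_genome):
        from oximap.clusters import detect_te_clusters
        from oximap.fractions import filter_topseq_calls, gene_mod_stats

        g = default_genome
        clusters = detect_te_clusters(g.tes, g.scaffolds)
        mod_sets = {"5hmC": filter_topseq_calls(g.modcalls["5hmC"], g.scaffolds)}
        df = gene_mod_stats(
            g.genes, g.cg_sites, mod_sets, expression=g.expression,
            tes=g.tes, clusters=clusters, scaffolds=g.scaffolds,
        )
        groups = {
            "in_cluster": df[df.in_cluster].tpm.tolist(),
            "clean": df[(~df.in_cluster) & (df.te_context == "clean")].tpm.tolist(),
        }
        _, p = group_compare(groups, "expression")
        assert p < 0.01

    def test_small_group_is_error(self):
        with pytest.raises(ConfigError):
            group_compare({"a": [1.0], "b": [1.0, 2.0]}, "fraction")
        with pytest.raises(ConfigError):
            group_compare({"a": [1.0, 2.0]}, "fraction")

    def test_two_group_kruskal_agrees_with_ranksum(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.3, 0.1, 400)
        b = rng.normal(0.35, 0.1, 400)
        _, p_kw = group_compare({"a": a, "b": b}, "fraction")
        _, p_mwu = pairwise_compare(a, b, "fraction")
        assert np.isclose(p_kw, p_mwu, rtol=0.05)


class TestExpressionByModification:
    @staticmethod
    def _table(rng, n, beta_mod, beta_cluster=-1.0, noise=0.4):
        frac_mc = rng.uniform(0, 1, n)
        frac_oxi = np.clip(frac_mc * 0.5 + rng.uniform(0, 0.5, n), 0, 1)
        frac_oxi[rng.random(n) < 0.1] = 0.0
        in_cl = rng.random(n) < 0.15
        y = 4 + beta_mod * frac_oxi + beta_cluster * in_cl + rng.normal(0, noise, n)
        tpm = np.maximum(2.0 ** np.maximum(y, 0) - 1, 0)
        return pd.DataFrame(
            dict(fraction_5mC=frac_mc, fraction_5hmC=frac_oxi, tpm=tpm, in_cluster=in_cl)
        )

    def test_negative_slopes_under_negative_effect(self):
        rng = np.random.default_rng(14)
        out = expression_by_modification(self._table(rng, 4000, beta_mod=-2.0))
        tr = out["trends"]
        big = tr[tr.n >= 50]
        assert len(big) >= 3
        assert (big.slope < 0).all()

    def test_null_effect_gives_flat_slopes(self):
        rng = np.random.default_rng(15)
        out = expression_by_modification(self._table(rng, 4000, beta_mod=0.0))
        tr = out["trends"]
        big = tr[(tr.n >= 200) & ~tr.in_cluster]
        assert (big.slope.abs() < 0.3).all()

    def test_none_bin_distinct_and_cells_cover_all_genes(self):
        rng = np.random.default_rng(16)
        df = self._table(rng, 1000, beta_mod=-2.0)
        out = expression_by_modification(df)
        cells = out["cells"]
        assert "none" in set(cells.oxi_group)
        assert cells.n.sum() == len(df)

    def test_low_fraction_beats_none_under_activation(self):
        """With a small positive effect of low modification over none, the
        low-fraction bin shows higher mean expression than the none bin."""
        rng = np.random.default_rng(18)
        n = 3000
        frac_oxi = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0.01, 0.1, n))
        y = 2 + 1.5 * (frac_oxi > 0) + rng.normal(0, 0.3, n)
        df = pd.DataFrame(
            dict(
                fraction_5mC=rng.uniform(0, 0.09, n),
                fraction_5hmC=frac_oxi,
                tpm=np.maximum(2.0**y - 1, 0),
                in_cluster=np.zeros(n, bool),
            )
        )
        cells = expression_by_modification(df)["cells"]
        sub = cells[~cells.in_cluster]
        none_mean = sub[sub.oxi_group == "none"].mean_expr.iloc[0]
        low_mean = sub[sub.oxi_group.str.startswith("(")].mean_expr.iloc[0]
        assert low_mean > none_mean


def rec(q, s, ident=96.0, cov=92.0, n_un=3.0, c_un=2.0):
    return ProteinAlignmentRecord(q, s, ident, cov, n_un, c_un)


class TestUniqueGenes:
    GENES = ["gA", "gB", "gC", "gD"]

    def test_similar_pair_collapses(self):
        out = unique_gene_filter([rec("gB", "gA")], self.GENES)
        assert out == {"gA", "gC", "gD"}

    def test_identity_below_threshold_keeps_both(self):
        out = unique_gene_filter([rec("gA", "gB", ident=94.0, cov=95.0)], self.GENES)
        assert out == set(self.GENES)

    def test_end_unmatched_above_threshold_keeps_both(self):
        out = unique_gene_filter([rec("gA", "gB", n_un=6.0)], self.GENES)
        assert out == set(self.GENES)

    def test_transitive_chain_single_representative(self):
        out = unique_gene_filter([rec("gA", "gB"), rec("gB", "gC")], self.GENES)
        assert out == {"gA", "gD"}

    def test_unknown_gene_is_error(self):
        with pytest.raises(ValidationError):
            unique_gene_filter([rec("gA", "gZ")], self.GENES)

    def test_idempotent_and_order_invariant(self):
        recs = [rec("gA", "gB"), rec("gC", "gB"), rec("gD", "gD")]
        out1 = unique_gene_filter(recs, self.GENES)
        out2 = unique_gene_filter(list(reversed(recs)), self.GENES)
        assert out1 == out2
        # filtering the surviving set again changes nothing
        surviving = [r for r in recs if r.query_id in out1 and r.subject_id in out1]
        assert unique_gene_filter(surviving, sorted(out1)) == out1

    def test_percentage_bounds_validated(self):
        with pytest.raises(ValidationError):
            ProteinAlignmentRecord("a", "b", 101.0, 90.0, 0.0, 0.0)
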
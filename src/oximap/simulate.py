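"""Synthetic fungal-like genomes with known modification structure.

The generator emulates the structure of a compact TE-rich genome and the
data types the pipeline consumes: scaffolds, non-overlapping gene models,
solitary TEs and dense TE clusters, CG sites with context-dependent
modification probabilities (TE > gene > intergenic), Seal-style fragment
pileups with a no-labelling control, WGBS counts, and TPM values whose
log-scale mean decreases with the gene's oxi-mC fraction and with TE
cluster membership.  Everything derives from one seeded NumPy PCG64
generator, so a fixed seed reproduces byte-identical output files.

The generated truth (cluster spans, per-gene fractions and effects) is
recorded in a manifest so downstream detectors and statistics can be
validated against construction rather than against themselves.

Geometric guarantees:

* planted clusters are runs of adjacent TEs (gaps <= 40 bp) spanning
  ``cluster_span`` bp, so local 100-bp TE content far exceeds 50% and the
  cluster detector must recover them;
* solitary TEs are kept >= 3 kb apart, at most 1.5 kb long and >= 10.5 kb
  away from planted clusters, which makes any merged run of them fail the
  50%-content/5-kb rule — no spurious clusters by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from oximap import io as oio
from oximap.core import (
    CGSite,
    ConfigError,
    ExpressionRecord,
    FragmentAlignment,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ModCall,
    Scaffold,
    TEFeature,
    WGBSCall,
)

OXI_MODS = ("5hmC", "5fC")

_TE_CATALOG = (
    ("I", "LTR", "Gypsy"),
    ("I", "LTR", "Copia"),
    ("I", "LINE", "L1"),
    ("I", "DIRS", "DIRS"),
    ("II", "TIR", "Mariner"),
    ("II", "RC", "Helitron"),
)

DEFAULT_P_MOD: dict[str, dict[str, float]] = {
    "5mC": {"TE": 0.60, "gene_nonTE": 0.15, "intergenic_nonTE": 0.10},
    "5hmC": {"TE": 0.40, "gene_nonTE": 0.10, "intergenic_nonTE": 0.05},
    "5fC": {"TE": 0.40, "gene_nonTE": 0.10, "intergenic_nonTE": 0.05},
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic genome; defaults emulate a small TE-rich
    fungal genome at desk scale."""

    seed: int = 0
    n_scaffolds: int = 2
    scaffold_len: int = 1_000_000
    gene_density: float = 3.0  # genes per 10 kb
    mean_gene_len: int = 1500  # bp
    te_density_solitary: float = 1.5  # TEs per 10 kb
    n_te_clusters: int = 3
    cluster_span: int = 8_000  # bp of dense TE run per planted cluster
    cg_rate: float = 25.0  # CG sites per kb
    p_mod: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(c) for m, c in DEFAULT_P_MOD.items()}
    )
    # expression model: log2(TPM+1) = alpha + beta_mod * oxi_fraction
    #                                 + beta_cluster * [in cluster] + noise
    alpha: float = 4.0
    beta_mod: float = -2.0
    beta_cluster: float = -1.0
    noise_sd: float = 0.5
    zero_expr_rate: float = 0.1  # Bernoulli mask of non-expressed genes
    # Seal fragments
    frag_depth: int = 5  # fragments per modified site
    background_rate: float = 0.5  # background fragments per 200 bp
    dup_rate: float = 0.1  # injected PCR-duplicate share
    # WGBS
    wgbs_depth: float = 10.0  # Poisson mean total reads per CG
    wgbs_meth_given_mod: float = 0.9
    wgbs_meth_given_unmod: float = 0.05
    # geometry safeguards
    solitary_te_len: tuple[int, int] = (150, 1500)
    solitary_min_gap: int = 3_000
    cluster_exclusion: int = 10_500  # solitary TEs kept this far from clusters

    def validate(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_len < 50_000:
            raise ConfigError("need >= 1 scaffold of >= 50 kb")
        for m, ctx in self.p_mod.items():
            for c, p in ctx.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"p_mod[{m}][{c}]={p} outside [0,1]")
        for name in ("zero_expr_rate", "dup_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0,1]")
        genome = self.n_scaffolds * self.scaffold_len
        gene_bp = self.gene_density * genome / 10_000 * self.mean_gene_len
        cluster_bp = self.n_te_clusters * (self.cluster_span + 2 * self.cluster_exclusion)
        if gene_bp > 0.6 * genome:
            raise ConfigError("gene density and length cannot be packed into the genome")
        if cluster_bp > 0.6 * genome:
            raise ConfigError("TE clusters cannot be packed into the genome")


@dataclass
class SyntheticGenome:
    """A generated genome plus every derived data layer and the truth
    manifest used by validation tests."""

    config: SyntheticConfig
    scaffolds: list[Scaffold]
    genes: list[GeneModel]
    tes: list[TEFeature]
    cg_sites: list[CGSite]
    cg_context: np.ndarray  # context label per CG site
    modcalls: dict[str, list[ModCall]] = field(default_factory=dict)
    wgbs: list[WGBSCall] = field(default_factory=list)
    expression: list[ExpressionRecord] = field(default_factory=list)
    fragments: dict[str, tuple[list[FragmentAlignment], list[FragmentAlignment]]] = field(
        default_factory=dict
    )
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def generate_genome(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Place clusters, solitary TEs, genes and CG sites on the scaffolds."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scaffolds = [Scaffold(f"scaffold_{i + 1}", config.scaffold_len) for i in range(config.n_scaffolds)]

    tes: list[TEFeature] = []
    cluster_cores: list[tuple[str, int, int]] = []
    te_counter = 0

    # planted clusters, round-robin over scaffolds
    per_scaffold: dict[str, int] = {s.id: 0 for s in scaffolds}
    for k in range(config.n_te_clusters):
        per_scaffold[scaffolds[k % len(scaffolds)].id] += 1

    margin = 6_000  # keep extended clusters off the scaffold edges
    spacing = config.cluster_span + 2 * config.cluster_exclusion
    for s in scaffolds:
        k = per_scaffold[s.id]
        if k == 0:
            continue
        usable = s.length - 2 * margin
        if usable < k * spacing:
            raise ConfigError(f"cannot place {k} clusters on scaffold of {s.length} bp")
        seg = usable // k
        for j in range(k):
            lo = margin + j * seg
            start = int(lo + rng.integers(0, max(1, seg - spacing)))
            end = start + config.cluster_span
            cluster_cores.append((s.id, start, end))
            cursor = start
            while cursor < end - 100:
                te_len = int(rng.integers(400, 1201))
                te_end = min(cursor + te_len, end)
                cls, order, fam = _TE_CATALOG[int(rng.integers(len(_TE_CATALOG)))]
                tes.append(
                    TEFeature(
                        f"te_{te_counter}",
                        GenomicInterval(s.id, cursor, te_end, "+" if rng.random() < 0.5 else "-"),
                        cls,
                        order,
                        fam,
                    )
                )
                te_counter += 1
                cursor = te_end + int(rng.integers(0, 41))

    # solitary TEs, kept away from clusters and from each other
    cluster_zones = {
        s.id: [
            (max(0, cs - config.cluster_exclusion), ce + config.cluster_exclusion)
            for scaf, cs, ce in cluster_cores
            if scaf == s.id
        ]
        for s in scaffolds
    }
    lo_len, hi_len = config.solitary_te_len
    for s in scaffolds:
        n_target = int(round(config.te_density_solitary * s.length / 10_000))
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_target and attempts < 50 * n_target:
            attempts += 1
            te_len = int(rng.integers(lo_len, hi_len + 1))
            start = int(rng.integers(0, s.length - te_len))
            end = start + te_len
            if any(start < ze and zs < end for zs, ze in cluster_zones[s.id]):
                continue
            if any(
                start - pe < config.solitary_min_gap and ps - end < config.solitary_min_gap
                for ps, pe in placed
            ):
                continue
            placed.append((start, end))
        placed.sort()
        for start, end in placed:
            cls, order, fam = _TE_CATALOG[int(rng.integers(len(_TE_CATALOG)))]
            tes.append(
                TEFeature(
                    f"te_{te_counter}",
                    GenomicInterval(s.id, start, end, "+" if rng.random() < 0.5 else "-"),
                    cls,
                    order,
                    fam,
                )
            )
            te_counter += 1

    # genes: non-overlapping bodies, uniform placement (may overlap TEs)
    genes: list[GeneModel] = []
    gene_counter = 0
    for s in scaffolds:
        n_target = int(round(config.gene_density * s.length / 10_000))
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_target and attempts < 50 * n_target:
            attempts += 1
            length = int(
                np.clip(rng.normal(config.mean_gene_len, config.mean_gene_len / 4), 400, None)
            )
            start = int(rng.integers(0, s.length - length))
            end = start + length
            if any(start < pe and ps < end for ps, pe in placed):
                continue
            placed.append((start, end))
        placed.sort()
        for start, end in placed:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _make_gene(f"gene_{gene_counter}", s.id, start, end, strand, rng)
            )
            gene_counter += 1

    # CG sites, uniform at cg_rate per kb
    cg_sites: list[CGSite] = []
    for s in scaffolds:
        n = int(round(config.cg_rate * s.length / 1000))
        pos = np.sort(rng.choice(s.length - 1, size=n, replace=False))
        cg_sites.extend(CGSite(s.id, int(p)) for p in pos)

    cg_context = _assign_contexts(cg_sites, tes, genes)

    extend = 5_000
    cluster_finals = [
        (scaf, max(0, cs - extend), min(config.scaffold_len, ce + extend))
        for scaf, cs, ce in cluster_cores
    ]
    manifest = {
        "cluster_cores": cluster_cores,
        "cluster_finals": cluster_finals,
        "n_genes": len(genes),
        "n_tes": len(tes),
        "n_cg": len(cg_sites),
    }
    return SyntheticGenome(
        config=config,
        scaffolds=scaffolds,
        genes=genes,
        tes=tes,
        cg_sites=cg_sites,
        cg_context=cg_context,
        manifest=manifest,
    )


def _make_gene(gene_id: str, scaffold: str, start: int, end: int, strand: str, rng: np.random.Generator) -> GeneModel:
    length = end - start
    n_exons = int(rng.integers(1, 4))
    if n_exons == 1 or length < 600:
        exons = [GenomicInterval(scaffold, start, end, strand)]
    else:
        cuts = np.sort(rng.choice(np.arange(100, length - 100), size=2 * (n_exons - 1), replace=False))
        bounds = [start, *(start + cuts).tolist(), end]
        exons = []
        for i in range(0, len(bounds) - 1, 2):
            if bounds[i] < bounds[i + 1]:
                exons.append(GenomicInterval(scaffold, bounds[i], bounds[i + 1], strand))
    utr_len = min(120, len(exons[0]) - 1, len(exons[-1]) - 1)
    utr5: list[GenomicInterval] = []
    utr3: list[GenomicInterval] = []
    if utr_len >= 20:
        first, last = exons[0], exons[-1]
        head = GenomicInterval(scaffold, first.start, first.start + utr_len, strand)
        tail = GenomicInterval(scaffold, last.end - utr_len, last.end, strand)
        utr5, utr3 = ([head], [tail]) if strand == "+" else ([tail], [head])
    return GeneModel(gene_id, GenomicInterval(scaffold, start, end, strand), tuple(exons), tuple(utr5), tuple(utr3))


def _assign_contexts(
    cg_sites: Sequence[CGSite], tes: Sequence[TEFeature], genes: Sequence[GeneModel]
) -> np.ndarray:
    """Context per CG with priority TE > gene_nonTE > intergenic_nonTE."""
    te_union = IntervalSet(t.location for t in tes)
    gene_union = IntervalSet(g.body for g in genes)
    ctx = np.full(len(cg_sites), "intergenic_nonTE", dtype=object)
    by_scaf: dict[str, list[int]] = {}
    for i, s in enumerate(cg_sites):
        by_scaf.setdefault(s.scaffold, []).append(i)
    for scaf, idx in by_scaf.items():
        pos = np.array([cg_sites[i].pos for i in idx])
        idx = np.asarray(idx)
        in_te = te_union.contains(scaf, pos)
        in_gene = gene_union.contains(scaf, pos)
        ctx[idx[in_te]] = "TE"
        ctx[idx[in_gene & ~in_te]] = "gene_nonTE"
    return ctx


# ---------------------------------------------------------------------------


def generate_modcalls(
    genome: SyntheticGenome, rng: np.random.Generator, n_replicates: int = 2
) -> dict[str, list[ModCall]]:
    """Bernoulli modification per CG by context; coverage 1 + Poisson(2).

    Each modified site is reported in ``n_replicates`` technical replicates
    (default two, mirroring the combined-replicate design the coverage
    filter expects); per-replicate coverage is drawn independently.
    """
    config = genome.config
    calls: dict[str, list[ModCall]] = {}
    for mod in sorted(config.p_mod):
        probs = np.array([config.p_mod[mod][c] for c in genome.cg_context], dtype=float)
        hit = rng.random(len(probs)) < probs
        idx = np.flatnonzero(hit)
        covs = 1 + rng.poisson(2.0, size=(len(idx), n_replicates))
        out = []
        for i, site_cov in zip(idx.tolist(), covs):
            site = genome.cg_sites[i]
            for r in range(n_replicates):
                out.append(ModCall(site, mod, int(site_cov[r]), sample_id=f"{mod}_rep{r + 1}"))
        calls[mod] = out
    genome.modcalls = calls
    return calls


def generate_wgbs(genome: SyntheticGenome, rng: np.random.Generator) -> list[WGBSCall]:
    """Bisulfite counts: total ~ Poisson(depth); methylated reads follow the
    site's true 5mC state with a small conversion error."""
    config = genome.config
    mc_sites = {c.site for c in genome.modcalls.get("5mC", [])}
    out: list[WGBSCall] = []
    totals = rng.poisson(config.wgbs_depth, size=len(genome.cg_sites))
    for site, total in zip(genome.cg_sites, totals):
        if total == 0:
            continue
        p = config.wgbs_meth_given_mod if site in mc_sites else config.wgbs_meth_given_unmod
        meth = int(rng.binomial(int(total), p))
        out.append(WGBSCall(site, meth, int(total)))
    genome.wgbs = out
    return out


def oxi_fraction_per_gene(genome: SyntheticGenome) -> dict[str, float]:
    """True oxi-mC fraction per gene: CGs carrying 5hmC or 5fC over all CGs
    in the gene body (0 when the body has no CG)."""
    oxi_sites: set[CGSite] = set()
    for mod in OXI_MODS:
        oxi_sites.update(c.site for c in genome.modcalls.get(mod, []))
    all_pos = _by_scaffold(genome.cg_sites)
    oxi_pos = _by_scaffold(oxi_sites)
    out: dict[str, float] = {}
    for g in genome.genes:
        total = _count(all_pos, g.body)
        out[g.gene_id] = _count(oxi_pos, g.body) / total if total else 0.0
    return out


def _by_scaffold(sites) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for s in sites:
        by.setdefault(s.scaffold, []).append(s.pos)
    return {k: np.sort(np.asarray(v)) for k, v in by.items()}


def _count(pos_map: Mapping[str, np.ndarray], iv: GenomicInterval) -> int:
    pos = pos_map.get(iv.scaffold)
    if pos is None:
        return 0
    return int(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))


def expected_log2_tpm(config: SyntheticConfig, oxi_fraction: float, in_cluster: bool) -> float:
    """Noise-free expression mean on the log2(TPM+1) scale."""
    y = config.alpha + config.beta_mod * oxi_fraction + config.beta_cluster * float(in_cluster)
    return max(y, 0.0)


def generate_expression(
    genome: SyntheticGenome, rng: np.random.Generator
) -> list[ExpressionRecord]:
    """TPM per gene from the linear log-scale model plus a zero mask."""
    config = genome.config
    fracs = oxi_fraction_per_gene(genome)
    finals = IntervalSet(
        GenomicInterval(scaf, s, e) for scaf, s, e in genome.manifest["cluster_finals"]
    )
    in_cluster = finals.overlaps_intervals([g.body for g in genome.genes])
    out: list[ExpressionRecord] = []
    truth = {}
    for g, in_cl in zip(genome.genes, in_cluster):
        y = (
            config.alpha
            + config.beta_mod * fracs[g.gene_id]
            + config.beta_cluster * float(in_cl)
            + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
        )
        y = max(y, 0.0)
        tpm = float(2.0**y - 1.0)
        if rng.random() < config.zero_expr_rate:
            tpm = 0.0
        out.append(ExpressionRecord(g.gene_id, tpm))
        truth[g.gene_id] = {"oxi_fraction": fracs[g.gene_id], "in_cluster": bool(in_cl)}
    genome.expression = out
    genome.manifest["gene_truth"] = truth
    return out


def generate_seal_fragments(
    genome: SyntheticGenome, rng: np.random.Generator
) -> dict[str, tuple[list[FragmentAlignment], list[FragmentAlignment]]]:
    """Sample/control fragment pileups per oxi modification.

    Sample: ``frag_depth`` fragments of 200-250 bp centred on every
    modified site, plus uniform background; control: background only.
    PCR duplicates are injected at ``dup_rate`` in the sample.
    """
    config = genome.config
    lengths = {s.id: s.length for s in genome.scaffolds}
    result: dict[str, tuple[list[FragmentAlignment], list[FragmentAlignment]]] = {}
    for mod in OXI_MODS:
        sample: list[FragmentAlignment] = []
        # replicate call lists share sites; fragments pile on unique sites
        sites = sorted({c.site for c in genome.modcalls.get(mod, [])})
        for site in sites:
            scaf_len = lengths[site.scaffold]
            for _ in range(config.frag_depth):
                L = int(rng.integers(200, 251))
                jitter = int(rng.integers(-50, 51))
                left = int(np.clip(site.pos - L // 2 + jitter, 0, scaf_len - L))
                sample.append(FragmentAlignment(site.scaffold, left, left + L, f"{mod}_sample"))
        sample.extend(_background(genome, rng, f"{mod}_sample"))
        n_dup = int(round(config.dup_rate * len(sample)))
        if n_dup and sample:
            picks = rng.integers(0, len(sample), size=n_dup)
            sample.extend(sample[int(i)] for i in picks)
        control = _background(genome, rng, f"{mod}_control")
        result[mod] = (sample, control)
    genome.fragments = result
    return result


def _background(genome: SyntheticGenome, rng: np.random.Generator, sid: str) -> list[FragmentAlignment]:
    config = genome.config
    out: list[FragmentAlignment] = []
    for s in genome.scaffolds:
        n = rng.poisson(config.background_rate * s.length / 200)
        lefts = rng.integers(0, s.length - 250, size=int(n))
        lens = rng.integers(200, 251, size=int(n))
        out.extend(
            FragmentAlignment(s.id, int(a), int(a + L), sid) for a, L in zip(lefts, lens)
        )
    return out


# ---------------------------------------------------------------------------


def simulate(config: SyntheticConfig | None = None, outdir: str | Path | None = None) -> SyntheticGenome:
    """Run the full generator; optionally write every layer to ``outdir``.

    All randomness flows from ``config.seed`` through one PCG64 stream in
    a fixed order, so identical configs give byte-identical outputs.
    """
    config = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    generate_modcalls(genome, rng)
    generate_wgbs(genome, rng)
    generate_expression(genome, rng)
    generate_seal_fragments(genome, rng)
    if outdir is not None:
        write_outputs(genome, outdir)
    return genome


def write_outputs(genome: SyntheticGenome, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    oio.write_scaffolds(out / "scaffolds.tsv", genome.scaffolds)
    oio.write_gene_models(out / "genes.gff3", genome.genes)
    oio.write_te_bed(out / "tes.bed", genome.tes)
    oio.write_cg_sites(out / "cg_sites.bed", genome.cg_sites)
    for mod, calls in genome.modcalls.items():
        oio.write_modcalls(out / f"modcalls_{mod}.bedGraph", calls)
    oio.write_wgbs(out / "wgbs.tsv", genome.wgbs)
    oio.write_expression(out / "expression.tsv", genome.expression)
    for mod, (sample, control) in genome.fragments.items():
        oio.write_fragments(out / f"fragments_{mod}_sample.bed", sample)
        oio.write_fragments(out / f"fragments_{mod}_control.bed", control)
    with open(out / "manifest.json", "w") as fh:
        json.dump(genome.manifest, fh, indent=2, sort_keys=True)
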
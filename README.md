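# oximap

Analysis of genome-wide 5mC / 5hmC / 5fC maps in transposable-element-rich
genomes.

Basidiomycete fungi such as *Laccaria bicolor* and *Coprinopsis cinerea*
carry large families of TET/JBP enzymes that oxidise 5-methylcytosine
(5mC) to 5-hydroxymethyl- (5hmC) and 5-formylcytosine (5fC).  Profiling
these oxidised marks combines three kinds of sequencing data: affinity
enrichment of labelled 5hmC/5fC fragments against a no-labelling control
("Seal"-type libraries), single-CG-resolution maps from tethered-
oligonucleotide-primed sequencing (TOP-seq), and whole-genome bisulfite
sequencing (WGBS) for the aggregate 5mC+5hmC signal.  `oximap` implements
the downstream analysis of such maps for compact, TE-rich genomes:

* **Seal window signal** — PCR-duplicate removal by fragment endpoints,
  equal-size downsampling, fragment coverage in non-overlapping 200-bp
  windows, and background subtraction: a window's modification level is
  `sample − control` wherever `sample ≥ 1.2 × control`, else 0.  Signal
  maps are compared as bin sets via the Jaccard coefficient
  `|A∩B| / |A∪B|`.
* **TE-cluster detection** — 100-bp windows with ≥ 25% TE content are
  merged (gap ≤ 100 bp) into cores, cores < 10 kb apart are merged,
  regions ≥ 5 kb long with ≥ 50% union-TE content are kept and extended
  by 5 kb on both sides.
* **Modification fractions** — per gene or region,
  `fraction = N_modCG / N_totalCG`, where a CG counts as modified when it
  survives the combined-replicate coverage ≥ 2 filter (TOP-seq, scaffolds
  > 100 kb only) or has methylation level > 50% at ≥ 5 reads (WGBS).
  Decile/quartile stratification uses non-zero values only.
* **Feature enrichment** — 2×2 tables of modified vs unmodified units
  (CGs or 200-bp bins) inside vs outside each genomic feature, tested
  with Fisher's exact test and reported as log2 odds ratios.
* **Gene–TE context and expression** — genes classified as
  clean / upstream / downstream / up+downstream / overlap by strand-aware
  TE proximity (< 1 kb); expressed means TPM > 0.05; group contrasts via
  Kruskal–Wallis / one-way ANOVA on log2(TPM+1); expression stratified
  jointly by 5mC and oxi-mC fraction groups; a protein-similarity filter
  (identity ≥ 95%, coverage ≥ 90%, ≤ 5% unmatched ends, transitive
  closure) collapses multi-copy genes to unique representatives.
* **Synthetic data** — a seeded generator builds miniature fungal-like
  genomes (genes, solitary TEs, planted TE clusters, CG sites with
  context-dependent modification probabilities, Seal fragment pileups
  with control, WGBS counts, TPM values) carrying known associations, so
  every stage is testable without sequencing data.

## Worked example

```python
from oximap.pipeline import run_pipeline
from oximap.simulate import SyntheticConfig

res = run_pipeline(SyntheticConfig(seed=1), outdir="out")
print(res["n_te_clusters"], round(res["te_log2_or_5hmC"], 2),
      round(res["spearman_expr_vs_oxi_fraction"], 2))
```

prints `3 3.17 -0.37`: on the default 2-Mb synthetic genome the detector
recovers the three planted TE clusters; 5hmCGs are enriched in TEs with a
log2 odds ratio of 3.17 — close to the closed-form value implied by the
generator's modification probabilities (`p(TE) = 0.4` against a non-TE
mix of 0.10/0.05) — and gene expression is negatively associated with the
gene oxi-mC fraction (Spearman ρ = −0.37), as built into the expression
model.  `out/` receives the per-window signal bedGraphs, cluster BED,
per-gene statistics table, enrichment table and summary JSON; identical
seeds give byte-identical files.

The same stages are available from the shell:

```sh
oximap simulate --seed 1 --out data/
oximap te-clusters --tes data/tes.bed --scaffolds data/scaffolds.tsv \
    --out clusters.bed --summary summary.tsv
oximap seal-signal --sample data/fragments_5hmC_sample.bed \
    --control data/fragments_5hmC_control.bed \
    --scaffolds data/scaffolds.tsv --out signal_5hmC.bedGraph
```

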
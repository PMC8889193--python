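# Methods

## Coordinates and units

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted at the I/O boundary in both directions.  A CG site is identified
by the position of its plus-strand C, and calls observed on either strand
of the dinucleotide collapse to that site: fraction statistics count CG
dinucleotides, not strand-specific cytosines.  Whether single-CG data
should instead be kept strand-resolved is an open choice; the collapse is
applied uniformly and documented here.

## Seal window signal

Fragments are deduplicated by exact (scaffold, leftmost, rightmost)
coordinates, keeping the first occurrence — the fragment-endpoint
definition of a PCR duplicate.  Libraries can be downsampled to a common
size (uniform, without replacement, seeded) before comparison.  Windows
tile each scaffold from position 0 in 200-bp steps; the trailing partial
window is kept and is shared by sample and control, so the comparison
stays fair.  "Coverage" of a window is the number of fragments overlapping
it by at least 1 bp: after endpoint deduplication the fragment is the
natural counting unit (a per-base mean is the plausible alternative; the
fragment count was chosen and is used consistently).  The background rule
is inclusive: signal = sample − control where sample ≥ 1.2 × control,
otherwise 0, and a window with control 0 and sample > 0 passes trivially
(any enrichment over an empty control is signal; this also avoids a
division).  Consequences: signal is always within [0, sample] and is
monotone in sample coverage at fixed control.

The false-positive rate of the 1.2× rule depends on control depth: at a
mean of λ fragments per window the probability that an unenriched sample
beats 1.2× control is roughly P(Z > 0.128·√λ), i.e. ≈ 24% at λ = 30 but
< 5% only for λ ≳ 165.  The background-control test therefore uses a deep
control (100 background fragments per 200 bp); with the sparse default
background the rule is intentionally noisy, as it would be for shallow
real libraries.

## TE clusters

The detector follows the window/merge definition exactly: (1) 100-bp
windows (grid anchored at 0, trailing window uses its actual length) with
TE content ≥ 25%, where content is union-TE bases over window length;
(2) selected windows merge into cores when their gap is ≤ 100 bp (one
unselected window between two selected ones therefore does not break a
core); (3) cores merge when separated by strictly less than 10 kb — the
two gap comparisons differ deliberately, following the "≤" versus "less
than" wording of the definition; (4) merged spans are kept when ≥ 5 kb
long with union-TE content ≥ 50% recomputed over the whole span (not a
mean of window fractions — this makes the detector invariant to TE
ordering and to splitting a TE into adjacent pieces); (5) survivors are
extended by 5 kb each side, clipped to scaffold bounds; (6) any extended
intervals that overlap are merged so membership queries are well defined
(after step 3 remaining gaps are ≥ 10 kb, so with 5-kb extensions this is
a no-op in practice; cluster counts are reported after the merge).
Member-TE counts use the pre-extension core.  Genome-level summaries
(total bp, genome fraction) use the final extended intervals.

The whole detector is validated against a literal brute-force
implementation (base-level boolean masks, every window materialised) on
hundreds of random toy genomes; the outputs must be interval-identical.

## Site filters and fractions

TOP-seq-style calls: technical replicates are combined by summing coverage
per site (sum rather than union — the choice is visible in
`combine_replicates`), then sites need combined coverage ≥ 2 and must lie
on scaffolds longer than 100 kb.  WGBS: sites need ≥ 5 reads; "modified"
means methylation level strictly above 50%.  The per-region fraction is
N_modCG / N_totalCG; a region without CGs is undefined (NaN) and excluded
downstream.  The complementary "coverage value" of a region is defined
here as the mean combined coverage over its modified CGs (0 when none);
the exact definition of this semi-quantitative measure is open, and the
mean was chosen as the simplest depth-weighted summary.  When the TOP-seq
scaffold filter is active, genes on scaffolds ≤ 100 kb are excluded from
gene-level statistics for consistency with the site filter.  Gene
fractions default to the full gene body; the 1-kb strand-aware upstream
interval (promoter proxy) is available as an alternative region.

Decile/quartile stratification excludes zero values before computing
edges.  Edges are empirical order statistics (NumPy `inverted_cdf`), and
a value equal to an edge falls in the lower group.  With distinct values
this puts each group within one member of n/k, ties always share a group,
and any order-preserving transform of the values leaves the grouping
unchanged.  Low/high flags mark the first and last decile of non-zero
values.

## Enrichment

Units (CG sites or 200-bp bins) are cross-classified as modified versus
not and inside versus outside each feature's interval union (CG: position
inside; bin: ≥ 1 bp overlap).  Feature membership is non-exclusive — a CG
in an exonic TE counts for both rows.  Fisher's exact test (two-sided,
`scipy.stats.fisher_exact`) gives the p-value; the effect size is the
sample odds ratio a·d / b·c, with the Haldane–Anscombe +0.5 correction
applied only when a cell is zero so the log2 odds ratio stays finite (the
p-value always uses raw counts).  Significance is raw p < 0.05 with no
multiple-testing correction, matching the figure convention;
Benjamini–Hochberg adjustment is available behind a flag.  Degenerate
tables (empty margin) are reported with `defined=False` rather than a
number.  The implementation is checked against exact integer
hypergeometric enumeration — same-margin tables share an integer-weight
denominator, so ties are decided exactly — over every 2×2 table with all
margins ≤ 30 (agreement to 1e−9; observed maximum deviation ~4e−16).

The standard feature classes derived from annotations are: exon, intron,
5′/3′ UTR, 1-kb upstream, TE (also split into gene-associated and
intergenic by gene-body overlap), repeats-excluding-TEs (user-supplied),
intergenic (complement of gene bodies), TE clusters (final intervals),
and an optional user-supplied TET-gene list.

## Gene–TE context and expression

TE context is exclusive with precedence overlap > up/downstream >
upstream/downstream > clean.  Upstream/downstream are strand-aware
relative to transcription direction, with a strict < 1 kb gap (a gap of
exactly 1 kb is clean).  The coarse label is TE+ iff any TE overlaps or
lies within the distance.  A gene is expressed when TPM > 0.05, strictly.

Omnibus comparisons use Kruskal–Wallis for fractions and one-way ANOVA on
log2(TPM+1) for expression; two-group contrasts use the Wilcoxon rank-sum
and t-test respectively.  A between-group variance of exactly zero makes
`f_oneway` return F = −0.0 with NaN p; this degenerate case is clamped to
(0, 1).  Expression-by-modification cross-tabulates genes into 5mC
fraction strata × oxi-mC fraction groups, with a dedicated "none" group
for genes with zero oxi-mC fraction (distinct from the lowest bin), and
is computed separately inside and outside TE clusters, which removes the
cluster effect as a confounder of the within-stratum trend.  The trend
per stratum is the least-squares slope of log2(TPM+1) on the oxi-mC
fraction, reported with its regression p-value; in strata where the
predictor has near-zero spread the raw slope is ill-scaled and only the
p-value is meaningful.

The unique-gene filter joins protein pairs with identity ≥ 95%, alignment
coverage ≥ 90% (query-side) and ≤ 5% unmatched residues at both ends into
connected components via union-find — similarity is made transitive, since
pairwise hits alone do not define a gene set — and keeps the
lexicographically smallest id per component, which makes the filter
deterministic, idempotent and order-invariant.

## Synthetic data generator

The generator emulates the *structure* of a TE-rich fungal genome, not
its sequence: scaffolds are coordinate spaces, there is no nucleotide
composition, TE nesting, or read-level error model.  Defaults (two 1-Mb
scaffolds; 3 genes per 10 kb with mean length 1.5 kb; 1.5 solitary TEs
per 10 kb of 150–1500 bp; three planted clusters of 8 kb dense TE runs;
25 CG sites per kb) give a 2-Mb genome with ~600 genes that runs through
the whole pipeline in seconds.  Modification probabilities per context
are 5mC 0.60/0.15/0.10 and 5hmC = 5fC 0.40/0.10/0.05 for
TE / gene (non-TE) / intergenic (non-TE); context priority is TE > gene >
intergenic, so CGs of TE insertions inside genes count as TE — this is
what couples TE presence to gene modification load.  Each modified site
is reported in two technical replicates with coverage 1 + Poisson(2)
each, so the combined-replicate coverage ≥ 2 filter retains every true
site, matching the combined-replicate design the filter expects.

Geometry guarantees that the constructed truth is recoverable: planted
clusters are runs of adjacent TEs (gaps ≤ 40 bp) whose content far
exceeds the 50% threshold, pairwise separated by ≥ 21 kb so they never
merge; solitary TEs are ≤ 1.5 kb, ≥ 3 kb apart and ≥ 10.5 kb away from
clusters (the window grid can shrink apparent gaps by up to ~200 bp, hence
the margin over the 10-kb merge distance), so any merged run of them
fails the 50%/5-kb rule — no spurious clusters by construction.

Expression follows log2(TPM+1) = α + β_mod·f_oxi + β_cluster·1[in
cluster] + N(0, σ), truncated at 0, with α = 4, β_mod = −2,
β_cluster = −1, σ = 0.5, where f_oxi is the gene's true oxi-mC (5hmC or
5fC) CG fraction; a separate Bernoulli mask (rate 0.1) sets genes to
TPM 0, modelling the distinct non-expressed class.  WGBS counts are
Poisson(10) totals with methylated reads Binomial(total, 0.9 | 0.05)
given the site's true 5mC state.  Seal samples place `frag_depth` = 5
fragments of uniform length 200–250 bp (jittered) on each modified site
over a uniform background of 0.5 fragments per 200 bp; controls are
background only; PCR duplicates are injected at rate 0.1.  All randomness
flows from one seeded NumPy PCG64 stream in fixed order, so a fixed seed
reproduces byte-identical output files across runs and platforms.

What passing tests on these data do and do not show: they demonstrate
that every rule is implemented exactly as defined and that configured
effects (context-dependent enrichment, cluster-linked silencing, negative
modification–expression association) are recovered at the configured
sizes; they do not validate behaviour under annotation errors, nested or
fragmented TEs, mapping artefacts, or genome-scale data volumes.

## Problem sizes and tolerances

Validation runs use 50-kb toy genomes (200 seeds) for detector–oracle
equivalence, the 2-Mb default genome for parameter recovery (~50 000 CGs;
binomial checks at 3 SE), 20 seeded 1-Mb replicates for odds-ratio
recovery (±0.3 around the closed-form log2 OR ≈ 3.663 implied by
p₁ = 0.4 vs p₀ = 0.05), a ~2000-gene cohort (four 1.25-Mb scaffolds,
eight clusters) for the expression contrasts (p < 0.01), and exhaustive
grids for the subtraction rule ({0..50}²) and Fisher's test (margins
≤ 30, 1e−9).  These sizes keep the full suite within a few minutes on one
CPU while leaving the statistical checks well powered.
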
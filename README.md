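# tempomod

Temporal expression modules from developmental RNA-seq time courses.

`tempomod` reimplements, as a tested and reusable pipeline, the analysis of a
bulk RNA-seq time course over the 96-hour starvation-induced developmental
program of *Myxococcus xanthus* DK1622 (7 time points — 0, 6, 12, 24, 48, 72,
96 h — in 2 biological replicates; raw reads at NCBI BioProject PRJNA493545).
Starting from a per-gene read-count matrix it produces quality-filtered
expression profiles, developmental/constitutive calls with a permutation
false-discovery rate, temporal modules ("developmental groups", DGs) ordered
by peak expression time, cross-dataset enrichment statistics, and
transcriptome-breadth summaries.  A synthetic-data generator with ground
truth stands in for the raw reads, so every stage is testable offline.

It is aimed at microbial transcriptomics researchers analysing developmental
or stress time courses with few replicates, where simple, transparent
threshold criteria are preferred over model-based differential expression.

## The method

**Quantification.**  Expression is measured in RPKM with an rRNA-excluded
library size (in a bacterial total-RNA library ~98% of reads are ribosomal):

```
rpkm(g, s) = reads(g, s) · 10⁹ / (length_bp(g) · clean_reads(s))
```

where `clean_reads = mapped − rRNA`.  Replicates are merged per time point
by the mean of the two replicate RPKMs.

**Developmental calling.**  A gene is *developmentally regulated* when
(1) every per-replicate, per-time-point count is ≥ 50 reads, (2) the two
replicate trajectories are concordant, r² (squared Pearson) > 0.7, and
(3) the merged trajectory changes more than 2-fold, max/min > 2.  Genes
passing (1)–(2) but not (3) are *constitutive*; the rest are filtered
(low / discordant / missing).

**Permutation FDR.**  The caller's false discovery rate is estimated by
scrambling the order of the time points — one uniform permutation per
replicate dataset per simulation, independent between replicates, shared
across genes — and re-running the caller:
`FDR = 100 · mean(scrambled passes) / observed passes` over 5 simulations.

**Modules.**  Developmental genes are transformed to log2 relative profiles,
`log2(rpkm_g,t / mean_t rpkm_g)`, clustered with seeded kmeans (Euclidean,
best of `n_init` restarts), and renumbered into DG1..DGK by ascending
centroid peak time.  For the canonical K = 10 the DGs map onto the
morphological phases: DG1–2 down-regulated, DG3–5 aggregation, DG6–7
aggregation→sporulation transition, DG8–10 sporulation.

**Enrichment.**  DG membership is cross-tabulated against an external
category set (e.g. a chemically induced sporulation transcriptome's
up1/up2/down/not-regulated classes) over the genes reliable in both
studies; each (DG, category) cell gets a 2×2 Pearson chi-square (1 df, no
continuity correction), significant at p < 0.01.

**Breadth.**  The breadth statistic at a time point is the minimal number of
top-expressed genes whose cumulative RPKM reaches 50% of the total — a
measure of how concentrated the mRNA pool is.

## Worked example

```python
import tempomod as tm

bundle = tm.simulate(tm.SimConfig(n_genes=2000, seed=42))   # synthetic study
et = tm.build_expression_table(bundle.counts, bundle.annotation, bundle.sheet)

calls = tm.call_regulation(et)
print(calls["class"].value_counts().to_dict())
# {'filtered_low': 1158, 'filtered_discordant': 417,
#  'developmental': 407, 'constitutive': 18, 'filtered_missing': 0}

fdr = tm.scramble_fdr(et, n_sims=5, seed=42)
print(round(fdr.fdr_pct, 2))          # 12.19  (407 observed passes)

dev = calls.index[calls["class"] == "developmental"]
profiles = tm.relative_profiles(et.rpkm_merged, dev)
model = tm.fit_clusters(profiles, k=10, seed=42)
dgs, centroids = tm.order_dgs(model, profiles)
print(dgs["dg"].value_counts().sort_index().to_dict())
# {1: 38, 2: 42, 3: 45, 4: 37, 5: 43, 6: 43, 7: 47, 8: 39, 9: 36, 10: 37}

print(tm.breadth50(et, 96).n_genes_50pct)   # 133
```

Of the 2000 synthetic genes, 425 (21.3%) pass the read-count and
replicate-concordance filters; 407 of those change more than 2-fold and are
called developmental, and kmeans organizes them into 10 peak-ordered
modules of 36–47 genes.  Scrambling the time points yields far fewer chance
passes than observed (FDR 12%), confirming the calls are driven by temporal
structure.  The same analysis runs from the shell:

```
tempomod run --config config.yaml --seed 42 -o outdir/
```

writing `sample_stats.tsv`, `rpkm_merged.tsv`, `regulation_calls.tsv`,
`fdr.tsv`, `dg_assignments.tsv`, `centroids.tsv`, `heatmap_matrix.tsv`,
`tally_report.tsv`, `breadth.tsv` (and `enrichment.tsv` when a category
table is supplied) plus a `manifest.json` with seeds and input digests.

The package also ships the published per-sample sequencing summary of the
DK1622 time course (`tempomod.datasets.load_dk1622_sample_sheet()`), from
which `sample_stats` reproduces the published per-sample rRNA rates
(e.g. 98.07% for WT_0_1), clean-read counts (1,296,267 for WT_48_1) and
genome coverage (13.05× at 100 bp reads over the 9,139,763 bp genome).

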
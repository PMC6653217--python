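# cistro

Integrative analysis of histone-modification and expression changes between
a lung-metastatic cancer cell line and its non-metastatic parental line,
built as a tested, reusable pipeline and exercised end-to-end on seeded
synthetic data with known ground truth.

The package is for computational biologists who want to reproduce, probe or
extend this style of integrative epigenome analysis — promoter chromatin
states, enhancer reprogramming, super-enhancer calling, motif-driven
regulatory networks and cohort-level validation — without needing the
original sequencing data: a first-class synthetic-data module emits every
input the pipeline consumes, plus the truth labels the analyses are
expected to recover.

## What it computes

Starting from per-cell, per-mark peak calls (H3K4me3, H3K27ac, H3K4me1,
H3K27me3, H3K9me3), BED gene models, an FPKM expression table, JASPAR-style
PWMs, GMT gene sets, and a cohort expression/survival table:

1. **TSS profiles** — tag density (tags per kb per million) in 200 bins
   over TSS ± 3 kb, averaged within expression deciles.
2. **Promoter states** — each TSS ± 2 kb window is *Active* (H3K4me3 or
   H3K27ac without H3K27me3), *Poised* (active mark + H3K27me3),
   *Repressive* (H3K27me3 only) or *None*; 4×4 transition counts between
   cells with the mean log₂ expression fold change per transition class.
3. **Differential enhancers** — H3K27ac peaks ≥ 2 kb from every TSS,
   merged across cells; a region is *gained*/*lost* when its library-scaled
   tag counts differ ≥ 4-fold with Poisson tail p < 10⁻⁴
   (p = P(Pois(min+1) ≥ max) on counts scaled to a common depth).
4. **Super-enhancers** — peaks stitched within 12.5 kb (TSS ± 2 kb
   excluded), regions ranked by summed signal; with rank and signal
   rescaled to [0, 1], the cutoff is the signal at the first one-rank
   secant whose slope exceeds 1, and regions above it are super-enhancers.
5. **Regulatory networks** — PWMs scanned (log-odds ≥ 0.8 × max score,
   both strands) over cell-specific active promoters/enhancers; motifs kept
   at hypergeometric enrichment p < 10⁻¹⁰; TF→gene edges labelled
   proximal/distal/both; TF–TF cooperation scored by the Jaccard index of
   target sets, with hubs defined as JI > 0.3 with > 10 partners.
6. **Cohort validation** — NMF (multiplicative updates, k = 2, best of 30
   restarts) clusters patients on the DEG panel; Pearson chi-square tests
   cluster–metastasis association; per-gene mean-split groups are compared
   by Kaplan–Meier curves and the log-rank test.
7. **Functional summary** — hypergeometric gene-set enrichment with
   Benjamini–Hochberg correction (FDR ≤ 0.05) and per-hallmark percentages
   of genes changed at the promoter, enhancer or expression layer.

DEGs are genes with ≥ 1.5-fold change and q < 0.05 throughout.

## Worked example

Generate a synthetic study and run two of the analyses (every step is also
available through the `cistro` CLI and `cistro.pipeline.run_all`):

```text
$ python analysis/01_simulate.py --seed 0
simulated 500 genes on one 20.1 Mb chromosome (seed 0) -> results/sim
  promoter-state pairs (A,B), top 5: [(('Active', 'Active'), 159), (('None', 'None'), 115),
  (('Repressive', 'Repressive'), 44), (('Repressive', 'Active'), 40), (('None', 'Active'), 33)]
  distal enhancers: {'gained': 46, 'stable': 188, 'lost': 51}; super-enhancer loci: {'stable': 3, 'lost': 7, 'gained': 15}
  planted TF->gene edges: 655; cohort: 404 patients

$ python analysis/03_promoter_states.py
classified 500 promoters -> results/promoters
  161 promoters changed state; 93 newly activated vs 50 de-activated in the metastatic cell
  mean log2 FC: Repressive->Active +3.14, None->Repressive -3.19 (activation up, repression down)

$ python analysis/07_cohort_validation.py
cohort validation (404 patients) -> results/cohort
  NMF (k=2, 30 restarts) cluster sizes: {1: 211, 0: 193}
  cluster vs metastasis chi-square: statistic 21.74, p 3.12e-06
```

Reading the numbers: 40 promoters switch Repressive→Active and those genes
shift up ~3 log₂ units while None→Repressive genes shift down ~3 — the
planted coupling between chromatin state and expression, recovered from the
emitted peak files alone.  Unsupervised NMF clustering of the simulated
patients on the DEG panel separates the latent groups, and the clusters
associate strongly with the metastasis label (chi-square p ≈ 3 × 10⁻⁶).

The numbered scripts under `analysis/` run the remaining stages (profiles,
enhancers, super-enhancers, networks, hallmark summary);
`cistro run-all --data results/sim --out results/run --seed 0` executes all
nine stages in one pass and writes a reproducibility manifest with a config
hash and per-output checksums (reruns with the same seed are
byte-identical).

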
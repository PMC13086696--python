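# nanopotency

Benchmark-concentration potency grouping and hazard identification for metal
oxide nanoparticles (MONPs), microparticles (MPs) and their dissolved metal
analogues, from in vitro concentration–response data.

## The problem

Regulatory screening of engineered nanomaterials needs a way to rank and
group many related compounds (e.g. ZnO, CuO, NiO, MnO₂, Al₂O₃, Fe₂O₃ and
TiO₂ in nano, micro and dissolved form) by toxicological potency using
non-animal data. This package implements that analysis as a reusable,
tested pipeline:

1. **Benchmark concentrations (BMCs).** For apical endpoints (viability,
   comet %DNA-in-tail, micronucleus frequency) a family of continuous
   dose-response models — null, `a·exp(b·xᵈ)` (exp3),
   `a·(c−(c−1)e^(−b·xᵈ))` (exp5) and Hill forms — is fitted by maximum
   likelihood with lognormal residuals, with the exposure timepoint as a
   covariate (level-specific background *a* and rate *b*; shared *c*, *d*
   and σ). The lowest-AIC model wins, exact ties going to the lower BMC.
   BMCs are solved at benchmark responses (BMR) of 5, 10, 25 and 50 %
   relative deviation from control and normalised to **µM constituent
   metal** (µg/mL ÷ molar mass × 1000 × metal atoms per formula unit).
2. **Transcriptomic points of departure (tPODs).** Genes with a significant
   Williams-type trend (isotonic/PAVA group means, permutation p < 0.05) and
   ≥ 1.5-fold change are fitted with an AIC-weight model average (normal
   residuals on log2 ratios); gene BMCs are solved at SD-based BMRs
   (1.021, 1.349, 1.932, 2.601 σ), and the pathway tPOD is the median gene
   BMC subject to a 3-gene minimum (or the NTP rule: ≥ 3 genes and ≥ 5 % of
   the pathway).
3. **Potency matrices.** Per BMR, a compounds × 7-endpoint matrix
   (24/48 h viability, 2/4 h comet, 40 h MN, 24/48 h tPOD); non-responsive
   cells are imputed at the top tested concentration, columns winsorized,
   values log10-transformed; the four matrices stack into the combined
   cross-BMR matrix (18 × 4 = 72 rows).
4. **Ensemble clustering.** 12 linkage × distance configurations
   (complete/average/single/Ward × euclidean/manhattan/minkowski) with
   multiscale bootstrap (nboot = 1000, relative sizes 0.4–1.4): per
   dendrogram node the approximately unbiased p-value AU = 1 − Φ(v − c) is
   fitted from the scale profile of bootstrap probabilities; AU > 0.95 marks
   supported clusters. Pairwise co-occurrence across attempts and a
   pooled-cluster Jaccard matrix yield potency groups as connected
   components of the thresholded similarity graph.
5. **Characterisation and hazard calls.** PCA (correlation convention,
   |loading| > 0.4 rule), Spearman endpoint–endpoint and Kendall τ-b
   endpoint–property associations, and four boolean hazard rules per
   compound (viability ≤ 66 %, MN ≥ 2-fold at ≥ 40 % viability,
   > 10 % DNA in tail, ≥ 3 responsive stress-pathway genes).

A first-class synthetic-data module generates all inputs from explicit
dose-response archetypes with known ground truth, so every stage is testable
offline.

## Worked example

```python
from nanopotency import RunConfig, run_pipeline

cfg = RunConfig(seed=17, out_dir="demo_out",
                compounds=("ZnCl2", "ZnO NP", "ZnO MP", "NiO NP", "TiO2 NP"),
                n_genes=40, n_permutations=100, nboot=100)
manifest = run_pipeline(cfg)
print(open("demo_out/hazard_report.txt").read())
```

prints the group-annotated hazard table (about a minute on one CPU):

```
    group  compound     death stress DNAbrk clast
        1  NiO NP           x      x      x     x
        1  ZnCl2            x      x      x     x
        1  ZnO MP           x      x      x     x
        1  ZnO NP           x      x      x     x
ungrouped  TiO2 NP          .      .      .     .
```

— the planted-toxic compounds form one potency group and carry positive
calls (viability at the top dose ≤ 66 % of control, ≥ 2-fold micronucleus
induction at viable concentrations, > 10 % tail DNA, ≥ 3 responsive
stress-pathway genes), while the inert TiO₂ particle stays ungrouped with
all-negative calls. The co-occurrence matrix (`demo_out/co_occurrence.tsv`)
shows the three Zn forms together in 83–100 % of the 48 supported-cluster
attempts and NiO joining them in 65 %:

```
         ZnCl2  ZnO NP  ZnO MP  NiO NP  TiO2 NP
ZnCl2     1.00    0.83    0.83    0.65      0.0
ZnO NP    0.83    1.00    1.00    0.65      0.0
ZnO MP    0.83    1.00    1.00    0.65      0.0
NiO NP    0.65    0.65    0.65    1.00      0.0
TiO2 NP   0.00    0.00    0.00    0.00      0.0
```

`demo_out/` also contains the per-BMR log10 µM-metal matrices, AU-annotated
Newick dendrograms, the Jaccard matrix, PCA loadings/scores and the full
run manifest.

The same stages are available from the shell:

```bash
nanopotency run --seed 17 --out demo_out
nanopotency cluster --matrix my_bmc_matrix.tsv --nboot 1000 --out clust_out
```

`cluster` accepts any compound × endpoint log10 BMC matrix in TSV form, so
externally published matrices can be re-clustered directly.

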
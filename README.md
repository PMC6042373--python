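# pafa

Population-aware prioritization and functional annotation of noncoding
variants.

Most supervised variant classifiers lean on conservation and chromatin
annotation, which works for coding and Mendelian variants but says little
about the common, weak-effect noncoding variants that drive complex
disease. `pafa` adds population differentiation as a first-class signal:
variants whose allele frequencies differ sharply between continental
populations are enriched for trait associations, while the bulk of
standing variation is not. The package provides, as a library and a CLI:

- **Population metrics** — the unbiased moment estimator of Wright's
  F_ST from per-subpopulation allele frequencies and sample sizes,

      F̂_ST = (MSP − MSG) / (MSP + (n_c − 1)·MSG),

  with MSG/MSP the within/between-population mean squares and n_c a
  variance-corrected average sample size; plus a dispersion score
  DS = √(Σᵢ (pᵢ − p̿)²/n), differentiation categories (little ≤ 0.05 <
  moderate ≤ 0.25 < large), and per-population frequency-preference
  calls.
- **Feature assembly** — a sparse variant × feature matrix over a stable
  registry: per-population allele frequencies, F_ST and DS; conservation
  scores; binary element-overlap features and TSS distance. Missing
  (no-overlap) entries are absent, never stored zeros.
- **Training-set curation** — pathogenic/benign conflict resolution,
  selection of element-overlapping trait-associated SNPs (p ≤ 1e−8),
  seeded sampling of low-F_ST (< 0.01) control candidates, ranking of
  "inversely associated" controls by a preliminary sparse model, ±50 bp
  adjacent-variant simulation, and seeded class balancing — with full
  survivor accounting per stage.
- **Scoring model** — L1-regularized logistic regression (liblinear);
  probability scores are the sigmoid of the sparse decision value.
  Evaluation by rank-based AUC and Wilcoxon rank-sum p-values, with
  stratified k-fold cross-validation.
- **Gene-centric annotation** — a weighted gene-disease score
  Sᵢ = sᵢ · min(1, Σⱼ (L_o/L_e)·W_T) over the elements a variant touches
  (weights: exon/TSS 1.0, UTRs 0.5, enhancer 0.3, TFBS 0.2, open
  chromatin 0.1).
- **VSEA** — variant-set enrichment analysis: map test and background
  variant sets to genes, test each pathway with a one-sided Fisher's
  exact test, adjust with Benjamini–Hochberg.
- **Synthetic data** — seeded generators (Balding–Nichols frequency
  tables, planted-signal cohorts, pathway fixtures) so the whole pipeline
  runs and is testable without any download.

See `docs/methods.md` for the models, defaults, and numerical decisions.

## Worked example

Compute F_ST and the dispersion score for two loci observed in three
populations (frequency table columns: `chrom, pos, p_<pop>…, n_<pop>…`,
sample sizes in allele copies):

```sh
$ cat freqs.tsv
chrom  pos   p_AFR  p_EAS  p_EUR  n_AFR  n_EAS  n_EUR
1      1000  0.72   0.18   0.22   1322   1008   1006
1      2000  0.31   0.30   0.29   1322   1008   1006

$ pafa fst --freq-table freqs.tsv --out fst.tsv
$ cut -f1,2,12,13,14 fst.tsv
chrom  pos   fst              ds               category
1      1000  0.3575744629     0.007367263993   large
1      2000  -0.0004119428494 0.0002448510534  little
```

The first locus (AFR frequency 0.72 vs ~0.20 elsewhere) is strongly
differentiated — F_ST 0.358 is well past the 0.25 "large" threshold, the
kind of population-specific signal the classifier rewards. The second
locus has essentially identical frequencies everywhere; its estimate is a
hair below zero (the unbiased estimator fluctuates around 0 at no
differentiation) and is categorized "little".

Run the whole flow on synthetic inputs — simulate a labeled cohort,
assemble features, cross-validate, train, score, annotate and test
enrichment:

```sh
$ pafa pipeline --out-dir demo --seed 7 --n-variants 600
INFO pafa: pipeline: featurized 600 variants x 219 features
INFO pafa: pipeline: CV mean AUC 0.9999, training AUC 1.0000
```

The planted cohort separates almost perfectly (tenfold CV mean AUC
0.9999) because the generator plants signal in all three feature classes;
`demo/` then contains the scored variants, the sparse model (TSV weights
+ JSON header), gene scores, the enrichment table and a checksum
manifest. Rerunning with the same seed reproduces every artifact
byte-identically.

Other subcommands: `simulate`, `featurize`, `train`, `score`, `eval`,
`curate` (YAML-configured), `annotate`, `vsea` — each writes headered TSV
and logs its effective thresholds to stderr.

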
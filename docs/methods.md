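# Methods

`pafa` prioritizes noncoding (and coding) variants with a supervised score
built on three feature classes — population differentiation, evolutionary
conservation, and genomic annotation — and annotates variants at the gene
and pathway level. This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate.

## Population-differentiation metrics

For a locus observed in `s` subpopulations with alternate-allele
frequencies `p_1..p_s` and sample sizes `n_1..n_s` (counted as sampled
allele copies), the unbiased moment estimator of Wright's fixation index is

    MSG  = [ Σ n_i p_i (1 − p_i) ] / (Σ n_i − 1)
    p̄    = Σ n_i p_i / Σ n_i
    MSP  = [ Σ n_i (p_i − p̄)² ] / (s − 1)
    n_c  = [ Σ n_i − (Σ n_i²)/(Σ n_i) ] / (s − 1)
    F̂_ST = (MSP − MSG) / (MSP + (n_c − 1) · MSG)

Numerical decisions:

- **MSG denominator.** The default divides by `Σ n_i − 1`; the classical
  moment-estimator form `Σ (n_i − 1)` is available via
  `msg_denominator="classical"`. For realistic sample sizes the two differ
  by O(s/Σn) and both recover the planted differentiation parameter in the
  generator tests.
- **Monomorphic loci.** When `MSP + (n_c − 1)·MSG = 0` the estimate is
  undefined; `fst_unbiased` flags it (`defined=False`, value NaN). Feature
  construction substitutes 0 for such loci — a fixed locus carries no
  differentiation signal — and this is the only place a missing value is
  ever converted to a stored 0.
- **Negative estimates.** The unbiased estimator is negative in expectation
  noise at low differentiation. Raw values are reported everywhere;
  feature construction clamps negatives to 0 (`clamp_fst=True`) so that
  the model sees values on a [0,1]-like scale.
- **Sample-size units.** `n_i` counts allele copies (haploid counts). Any
  consistent unit only rescales `n_c`; the simulators and tests use the
  same convention throughout.

The dispersion score summarizes frequency spread around the *unweighted*
mean `p̿ = Σ p_i / s`:

    DS = sqrt( Σ (p_i − p̿)² / n ),  n = Σ n_i.

The denominator is the total sample size, not `s`; DS is defined
operationally, not as a textbook standard deviation, and is implemented as
printed. It is 0 iff all `p_i` are equal.

Differentiation categories use the conventional thresholds with closed
lower bounds: little (F_ST ≤ 0.05), moderate (0.05 < F_ST ≤ 0.25), large
(F_ST > 0.25). Per-population preference calls flag a population whose
frequency exceeds (or falls below) every other population's by a margin,
default 0.10. The plain average sample size `n̄ = Σ n_i / s` is stored on
`PopulationFrequencyTable` for completeness but enters no formula; the
estimator uses the variance-corrected `n_c`.

## Feature assembly

Features live in a registry that assigns each name a fixed, contiguous,
1-based index that is never reassigned — matrices produced under the same
registry are comparable, and the registry fingerprint is stored on trained
models to prevent accidental mixing.

Three feature classes:

- **Population** (group `population`): one allele-frequency feature per
  subpopulation, plus F_ST (clamped) and DS. A variant absent from the
  frequency resource has all seven features missing.
- **Conservation** (group `conservation`): one numeric feature per score
  track (e.g. phastCons/phyloP over 46 and 100 vertebrates); an absent
  position is missing, a stored 0.0 is a real score.
- **Annotation** (group `annotation`): one binary feature per element
  track (histone marks, RNA contigs, TFBS PeakSeq/SPP, open chromatin,
  TSS, …) — 1.0 on overlap, missing otherwise. Presence/absence is the
  default because it is the only information an interval track guarantees;
  an overlap-fraction mode exists per track. The TSS-distance feature is
  the raw absolute bp distance to the nearest TSS start (0 inside a TSS),
  optionally log10(1+d).

**Missing vs zero.** A missing feature is absent from the sparse row; the
linear decision function gives absent entries a 0 contribution — that is
the operational meaning of "missing" in the model — but the matrix and its
svmlight serialization never conflate a stored 0.0 with absence.

Coordinates are handled in a single internal convention (0-based
half-open); VCF positions are converted on read, BED intervals pass
through unchanged, and `chr` prefixes are stripped so VCF- and BED-derived
names compare equal. Overlap is strand-agnostic. A variant's footprint is
its reference-allele span (1 bp for SNVs, which are the tested path;
indels are a best-effort extension).

## Training-set curation

The curation flow assembles balanced labeled sets from heterogeneous
sources:

1. Records labeled both pathogenic and benign are kept functional and
   dropped from the control side.
2. Trait-associated SNPs with association p ≤ 1e−8 that overlap at least
   one known genomic element join the functional set.
3. Up to k = 100,000 variants with defined F_ST < 0.01 (and keys not
   already used by either side) are sampled, seeded, as control
   candidates.
4. A preliminary L1-logistic model — candidates as the negative class,
   the selected trait-associated SNPs as positives — ranks candidates by
   signed decision value; the m most negative ("inversely associated")
   become controls. Only strictly negative scores qualify; a shortfall is
   reported, not papered over. Ties are broken by variant key for
   reproducibility. The candidate pool itself is the negative class
   because it is the only variant pool present at that stage, and it makes
   "negative output = inversely associated" well defined.
5. Optionally, simulated rare variants adjacent to the functional anchors
   (uniform in ±50 bp, excluding the anchor position; reference
   placeholder `N`) join the controls. The same ±50 bp simulator doubles
   as the adjacent-control generator used in evaluation.
6. The larger class is down-sampled (seeded) to the smaller one's size.

Every stage's survivor count is recorded in `provenance_counts`, so
|input| = |kept| + |removed| is checkable at each step. Variant identity
is the (normalized chrom, pos, ref, alt) key throughout. Recurrence
labeling counts *distinct* donors (≥ 2 by default).

## Scoring model

L1-regularized logistic regression, fit with the liblinear coordinate-
descent solver (tolerance 1e−6, seeded). The L1 penalty produces exact
zeros for uninformative features; a variant's score is
`sigmoid(intercept + Σ w_i x_i)` over its stored features. No feature
standardization is applied before fitting (documented choice: binary and
[0,1]-scaled features dominate the default registry). Class weights are
uniform because curation balances the sets. C defaults to 1.0;
`select_regularization` picks C from {0.01, 0.1, 1, 10} by stratified CV
AUC under a one-standard-error-style rule with an absolute slack floor
(0.005 AUC): the smallest C within max(1 SE, 0.005) of the best. The
floor matters because on strongly separable data the CV curve is flat
near its maximum and the fold-to-fold SE collapses to ~1e−4, which would
otherwise defeat the sparsity-seeking intent of the rule.

Evaluation uses the rank-based (Mann–Whitney) AUC with ties counted 1/2
and the Wilcoxon rank-sum p-value under the tie-corrected normal
approximation. For group sizes down to 2 the approximation tracks exact
permutation enumeration within a `0.25/min(n_a, n_b)` envelope, which is
the tolerance the tests assert.

## Gene-centric annotation score

A variant touching elements of genes `i = 1..m` scores

    score = Σ_i S_i,   S_i = s_i · min(1, Σ_j (L_o_ij / L_e_j) · W_T(type_j))

with `s_i` the gene's occurrence count across the configured gene-disease
tables (raw counts, summed over tables), `L_e` the element length, `L_o`
the overlap length, and element-type weights W_T: exon 1.0, TSS 1.0,
3′/5′-UTR 0.5, enhancer 0.3, TFBS (PeakSeq/SPP) 0.2, open chromatin 0.1.
The cap wraps the whole weighted sum — the only reading that keeps
S_i ≤ s_i. Elements reached through multiple transcripts are deduplicated
by (gene, type, interval) before summation. The weights are configuration
with these values as defaults; new element types may be added with an
explicit weight.

## Variant-set enrichment (VSEA)

Test and background variant sets are mapped to the genes whose elements
they overlap (gene-level counting: a gene hit by many variants counts
once), and each pathway is tested with a one-sided Fisher's exact test on
the 2×2 table (test in/out of pathway vs background in/out), with
Benjamini–Hochberg adjustment across pathways reported alongside raw p.
The background is a *comparison group*, not a universe containing the
test set: folding test genes into the background would make the table's
rows dependent and the hypergeometric null conservative by almost an
order of magnitude, so the two sets are used exactly as given (stray test
genes are logged). One-sided enrichment is the default; the alternative
is a flag.

## Synthetic-data generators

All generators are pure functions of a `SimulationConfig` (seed
included).

- **Frequency tables** follow the Balding–Nichols model: ancestral
  frequency p0 ~ Uniform(0.05, 0.95), subpopulation frequencies
  `p_i ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, observed frequencies binomial
  draws of `n_i = 500` allele copies — binomial sampling so the
  estimator's finite-sample corrections are actually exercised. Defaults:
  5 subpopulations, 5,000 loci, F = 0.1. The estimator's mean over 5,000
  loci recovers a planted F = 0.1 within ±0.02 and stays below 0.01 at
  F = 0.001 (the near-zero limit).
- **Training cohorts** (default n = 2,000, half functional) plant signal
  in all three feature classes: 10 informative tracks overlap functional
  variants with probability 0.8 vs 0.2 for controls (base 0.5 ±
  effect/2, effect 0.6); 200 noise tracks overlap both at 0.3; two
  conservation tracks are shifted by ±0.3·effect around 0.5 (sd 0.15,
  10% missing); functional loci draw Balding–Nichols frequencies at
  F = 0.02 + 0.18·effect, controls at F = 0.02. Each variant sits on its
  own locus and each track's intervals are constructed around exactly
  the variants it overlaps, so overlap indicators are independent
  Bernoulli draws with exactly the stated probabilities. Setting
  `effect_size = 0` makes the classes exchangeable (a null cohort).
- **Pathway fixtures** place one 200 bp exon per gene (2,000 genes over
  two 1 Mb chromosomes), draw 20 overlapping 200-gene pathways, and
  sample disjoint test (400) and background (1,000) gene sets, one
  variant per selected gene. With planting, 30% of test genes come from
  the first pathway. The sizes are deliberately large enough that the
  hypergeometric null is near-continuous; Fisher's exact test is
  conservative on small tables, and calibration (fraction of raw
  p < 0.05 ≈ 0.05) is only observable away from the discrete regime.

**What the synthetic tests show — and don't.** They demonstrate estimator
correctness against the closed-form arithmetic, parameter recovery under
the generative model the estimator assumes, classifier recovery of
planted, conditionally independent signals, exact survivor accounting in
curation, and calibrated/powered enrichment testing. Real data differ in
ways the generators deliberately omit: linkage disequilibrium between
loci, correlated annotation tracks, cell-type structure, mutation-rate
heterogeneity, ascertainment bias in GWAS panels, and label noise in
curated databases. Passing these tests certifies the machinery, not the
published discrimination performance on any particular database
snapshot.

## Problem sizes in the packaged checks

The shipped acceptance script and test suite run the generators at the
defaults above (5,000 loci; cohorts of 2,000; 100 enrichment replicates;
end-to-end pipeline at 300–600 variants), sizes at which every planted
quantity is comfortably identifiable on a single CPU in a few minutes.

## Known limitations

- Only point variants are exercised; indel footprints are handled by the
  reference-span rule but untested against real annotation; structural
  variants are out of scope.
- No haplotype or sliding-window F_ST, and no per-SNP bootstrap CIs.
- The svmlight serialization stores indices sparsely; models refuse to
  score matrices whose registry fingerprint differs, but no schema
  migration is provided.
- In-memory interval indexing is the intended scale (desk-scale fixture
  and cohort sizes), not tabix-backed genome-wide annotation.
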
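# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `rhizoeval`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design assumed

A completely randomized design with ≥2 treatments (default
`Ctrl, BA, FS, BA-FS`: untreated control, basal application, foliar spray,
and their combination) and ≥2 replicates per treatment (default 5). Two
amplicon communities (bacterial 16S-like and fungal ITS-like) are analyzed
in parallel; indicator tables carry replicate-level soil physicochemistry
and leaf yield/quality values.

## Diversity

* **Rarefaction** subsamples each sample without replacement
  (multivariate hypergeometric draw) to the minimum library size, in a
  single draw with a recorded seed. Averaging over draws is deliberately
  not done; a single seeded draw is the common practice in amplicon
  pipelines and keeps every downstream stage bit-reproducible.
* **Simpson index** is reported in its dominance form D = Σ pᵢ² (higher D
  = lower diversity); the complement 1 − D is available. D is invariant to
  count scaling.
* **Bray-Curtis** BC = Σ|x−y| / Σ(x+y) is a semimetric in [0, 1]; the
  triangle inequality is not guaranteed and never assumed.
* **PCoA** Gower-centers −D²/2 and eigendecomposes. Negative eigenvalues
  (possible because Bray-Curtis is non-Euclidean) are excluded both from
  the coordinates and from the explained-variance denominator, so
  percentages refer to the representable variation only.
* **PERMANOVA** uses Anderson's one-way pseudo-F computed directly from
  squared distances (SS_T = Σ_{i<j} d²ᵢⱼ/n, SS_W summed per group with
  1/n_g). The p-value permutes labels freely and uses the add-one
  estimator (1 + b)/(1 + m), which cannot return 0; with m = 999 the floor
  is 0.001. Tree-based metrics (UniFrac) are out of scope — no phylogeny
  is consumed — so Bray-Curtis backs both the ordination and the group
  test.
* **Wilcoxon rank-sum** routes to exact enumeration for n+m ≤ 12 without
  ties and to the tie-corrected normal approximation otherwise.

## Co-occurrence networks

* Built **per treatment** (one network per treatment, as in comparative
  field studies), with prevalence filtering (>50 % of **all** samples,
  strict) applied before splitting. With n = 5 replicates per treatment the
  p < 0.05 gate at df = 3 requires |r| ≳ 0.878, i.e. the p-gate is binding
  over the |r| > 0.80 gate. This is a documented property of the design,
  not something the package "corrects".
* Correlations are Pearson (Spearman optional) on relative abundances;
  p-values from the t transform with df = n−2. No multiple-testing
  correction is applied to edge p-values, mirroring the thresholding
  convention this pipeline reproduces. Zero-variance taxa yield missing
  correlations and can never form edges.
* **Topology**: average degree 2E/N over all retained nodes; average path
  length over connected pairs only (the Gephi convention for disconnected
  graphs); modularity by networkx's seeded Louvain at resolution 1.0, best
  of 10 restarts, on the unweighted graph; mean local clustering (degree <2
  contributes 0); the network-level eigenvector-centrality aggregate is the
  mean node centrality, computed by deterministic power iteration on the
  largest connected component, L2-normalized, with non-component nodes
  contributing 0 (published tables print a single unexplained aggregate;
  the mean is this package's fixed choice). Edge-sign percentages are
  rounded to 2 d.p. with the rounding remainder assigned to the larger
  class so they always sum to exactly 100.
* **Robustness**: for removal fractions 0–0.5 (step 0.05), ⌊fN⌋ nodes are
  removed uniformly at random and the largest-component size relative to
  the original N recorded, averaged over repetitions; the AUC is the
  trapezoid integral normalized by the fraction span, hence in [0, 1].
  Standard modularity is bounded by 1; published modularity values above 1
  cannot arise from this definition and are treated as report inputs only.

## Conformity (fuzzy membership) evaluation

* **Membership** u is linear min-max over **treatment means** (the score
  compares treatments; replicate data feed the weights and the ANOVA).
  Benefit: (x−min)/(max−min); cost: reversed; a constant indicator maps to
  0.5 everywhere. Cost-direction defaults: proportion of low-grade leaves,
  leaf starch, leaf total sugars. Soil nutrient contents are
  benefit-direction; pH carries no direction and is excluded from scoring.
* **Weights** wᵢ ∝ mean_{j≠i} |r_ij| on replicate-level data (Pearson by
  default, Spearman optional), normalized to Σw = 1.
* **Composite score** S_t = Σᵢ wᵢ u_{t,i} ∈ [0, 1]; percent improvement is
  reported vs. the designated control (undefined — reported missing — when
  the control scores exactly 0, which happens whenever the control is worst
  on every directed indicator). Because min-max over treatment means pins
  at least one treatment to 0 per indicator, absolute score levels are tied
  to the normalization domain; the treatment ranking is the stable output.
  A sigmoidal membership or replicate-domain normalization would change the
  levels, not the ordering; linear min-max over means is the fixed default.
* **Group comparison**: one-way ANOVA; if significant at α, Tukey HSD
  (studentized range) pairwise p-values feed an insert-and-absorb compact
  letter display with "a" on the highest mean; otherwise all treatments
  share "a". All-zero within-group variance with unequal means is flagged
  `degenerate` and given all-distinct letters without a test.

## Environmental association

* **Factor distance**: Euclidean on z-scored factors (population SD), so
  the matrix is invariant to affine rescaling of any factor's units.
* **Mantel**: Spearman correlation of the two off-diagonal vectors; null by
  simultaneous row/column permutation of the second matrix; one-sided
  "greater" by default (the convention of the vegan ecosystem), two-sided
  optional; add-one p estimator, exact enumeration available for n ≤ 8.
  Because a simultaneous permutation only re-pairs off-diagonal entries,
  ranks are computed once and permuted — exactly equivalent, much faster.
* **Factor panel**: pairwise Spearman ρ with two-sided p (exact permutation
  null for n ≤ 9 untied samples, t approximation otherwise); stars
  * p<0.05, ** p<0.01, *** p<0.001. The panel is reported unadjusted, with
  a Benjamini-Hochberg column emitted alongside for users who want it.

## Synthetic-data model

The generator emulates the statistical structure the analyses assume, not
sequencing reads (no error/chimera model, no phylogeny).

* **Communities**: per treatment, a composition over `n_taxa` taxa
  (bacterial default 320, fungal 160 — deliberately desk-scale relative to
  real ASV inventories in the tens of thousands; all statistics scale in
  the number of taxa, not in anything the tests assert). The dominant
  genus takes a fixed expected share: fungal pathogen analog 0.60 in the
  control (within the 55.4–65.0 % dominance window such communities show),
  multiplied by 0.94/0.96/0.88 under BA/FS/BA-FS — the combined treatment
  suppresses the pathogen analog hardest, consistent with reductions of a
  few to ~12 %; bacterial dominant 0.29, enriched ×1.15/1.10/1.30.
  Remaining mass is log-normal (σ = 1.5) with per-treatment multiplicative
  effects exp(N(0, 1)) on a random 30 % of taxa — a strong, clearly
  separated treatment signal. Per sample: Dirichlet (concentration 300)
  replicate noise, lognormal depth (median 20 000 reads, log-sd 0.25, so
  rarefaction always has work to do), multinomial counts.
* **Indicators**: replicate values ~ Normal(mean, SD) truncated at zero,
  with the soil defaults taken verbatim from the published field-trial
  table (10 soil properties × 4 treatments, mean ± SD, n = 5). The leaf
  defaults are **synthetic stand-ins** (the replicate-level leaf tables are
  not published): control baselines with treatment shifts matching the
  reported percent changes in yield, low-grade proportion, K, alkaloids,
  starch and sugars.
* **Determinism**: all draws flow through numpy's PCG64; stage seeds are
  `SeedSequence(seed, spawn_key=(k,))` children truncated to 31 bits, so
  stages can be re-run in isolation.

What passing tests on this generator do **not** show: behaviour under
compositional artefacts of real amplicon data (spurious correlation from
closure is present but not adversarially modelled), taxonomic misannotation,
batch effects, or the much weaker effect sizes real treatments often have.
The type-I-error simulations (PERMANOVA, Mantel) are the exception — they
use i.i.d. null data and hold regardless of the generator.

## Problem sizes and tolerances

Default analysis sizes (20 samples, ≤320 taxa, 999 permutations, 50–100
robustness repetitions) complete in seconds; the Monte-Carlo test batteries
use 100–200 repetitions with 199 permutations each, sized so the whole
suite runs in well under a minute of simulation time. Numerical
tolerances: PCoA reconstruction 1e-9 on Euclidean input; relative-abundance
column sums 1e-12; weight normalization 1e-12; PCoA eigenvalue positivity
cutoff 1e-10 relative to the spectral radius.

## Known limitations

* No phylogenetic β-diversity (UniFrac) — by design, no tree is consumed.
* Correlation networks on n = 5 samples are dominated by the significance
  gate and are unstable in edge identity (not in the summary statistics the
  tests assert); treat per-treatment edge lists as descriptive.
* The conformity score's absolute level is normalization-relative (see
  above); only differences/rankings between treatments are interpretable.
* The robustness statistic (random-removal giant-component AUC) is one of
  several used in the literature (targeted removal, natural connectivity);
  alternatives are not implemented.
* BIOM/FASTQ input, SparCC/SPIEC-EASI compositional networks, partial
  Mantel and db-RDA are out of scope.
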
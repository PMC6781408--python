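# Methods

This note documents the models implemented in `spgwas`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical and design decisions a maintainer should know about. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The experimental design being modeled

One heterogeneous, random-mating population (an open-pollinated landrace) is
planted in four ~0.1-ha plots of 5000 plants. In each plot, 96 plants are
sampled for genotyping-by-sequencing (GBS) and measured for height. From the
sampled phenotype distribution a ~5% truncation threshold is set per plot;
every plant beyond the threshold (tall in two plots, short in the other two)
is harvested as a seed parent. The open-pollinated offspring are grown the
next year in the same plots and sampled the same way. The 768 sampled plants
of both generations form the association panel; the 384 generation-1 samples
form the tall and short in-silico bulks for BSA (they are the offspring of
the generation-0 phenotypic tails, hence enriched/depleted for trait
alleles).

## Simulator (`simpop`)

**Founders.** Per marker, a base alt-allele frequency is drawn uniformly on
[0.05, 0.95]; each individual receives two independent Bernoulli gametes,
so dosages are Binomial(2, f) — Hardy-Weinberg proportions and linkage
equilibrium between markers. Markers sit on an evenly spaced physical grid
(default 5 chromosomes × 400 markers over 150 Mb) with a constant genetic
map of 1 cM/Mb.

**Trait.** Strictly additive: `height = 180 cm + plot-year effect +
Σ_j dosage_j · effect_j + e`, `e ~ N(0, σ²_e)`. QTL are a random marker
subset (default 40) with Normal(0, 3 cm) effects; σ_e is solved once, on
generation 0, so that realized Var(G)/Var(P) equals the target narrow-sense
heritability (default 0.75). The realized ratio is recorded as the ground
truth `true_h2`. Default plot-year effects are fixed offsets of up to
±8 cm, the order of the plot-mean differences a multi-location field trial
shows. Measurements can optionally be rounded to 5 cm to mimic measuring
sticks; rounding is off by default.

**Selection and mating.** The truncation threshold is the empirical
(1 − fraction) quantile (tall; the fraction quantile for short) of the
*sampled* plants of a plot, then applied to the whole plot; plants exactly
at the threshold are included. Parents mate at random with replacement —
selfing allowed, as open pollination includes self pollen and its effect is
negligible at hundreds of parents. Gametes recombine between adjacent
markers with Haldane probabilities `r = (1 − e^(−2d))/2` (d in Morgans);
chromosomes assort independently.

**GBS observation.** Depth per call is Poisson (default mean 2.01); zero
depth is a missing call; a heterozygote covered by d reads is miscalled
homozygous when all reads carry one allele (probability `2^(1−d)`);
homozygotes are read correctly. Sequencing error is not modeled (no error
rate is specified for the emulated protocol). Per-marker total read counts
feed the read-count filter.

**Seeding.** One master seed; per-stage generators are spawned from a
`SeedSequence`, so identical configs reproduce bit-identical outputs.

**What the simulator does not emulate.** Founder linkage disequilibrium:
markers are drawn independently, so LD exists only through the one
generation of transmission. In real landraces, selection drags linked
haplotype blocks and BSA regions span them; here a selected QTL produces a
sharp single-marker frequency spike, and regions arise from the 15-SNP
smoothing window around that spike. Passing end-to-end tests therefore
demonstrate that the scan/threshold/smoothing/region machinery recovers
planted signals — not that region *widths* match what founder LD would
produce. Also absent: mutation, dominance, epistasis, spatial field trends,
pollen contamination between plots, and any demography beyond one selection
cycle.

## Genotype handling (`geno`)

Dosage matrices hold {0, 1, 2} alt-allele counts with −1 (integer) or NaN
(float) for missing; coordinates are 1-based inclusive, as in VCF. Marker
filtering follows the exclusion rules "MAF below 0.05" and "total read count
below 40" with *strict* boundaries: a marker at exactly MAF 0.05 or 40 reads
survives. The read count is interpreted as reads summed over all samples at
the marker (the natural reading for a cohort-level filter). Filtering is
idempotent. Missing calls are imputed by the marker mean dosage — a
deliberate, dependency-free replacement for haplotype-aware imputation;
downstream dosages are therefore real-valued. The GRM is `Z Zᵀ / m` on
dosages standardized by `(d − 2p)/sqrt(2p(1−p))`, monomorphic markers
dropped. PCA is an eigendecomposition of the GRM with coordinates scaled by
the square root of the eigenvalue.

## Phenotypes and heritability (`pheno`)

Standardization residualizes heights on plot-year cells (8 cells in the
default design); with one factor the fitted value is the cell mean, so
residuals sum to zero per cell by construction. Singleton cells get residual
0 with a warning.

`realized_h2` is `R/S` clamped to [0, 1] (clamping logged): `S` is the
selected-parent mean minus the base mean, `R` the offspring mean minus the
base mean. On real data the year-to-year environment shift contaminates `R`;
in simulation mode the pipeline removes the known plot-year effects before
forming the ratio, isolating the genetic response.

`greml_h2` fits `y = Xb + g + e`, `g ~ N(0, σ²_g · GRM)` by REML. The GRM is
eigendecomposed once; the restricted log-likelihood is profiled in
`λ = σ²_g/σ²_e` and maximized by bounded search on `log λ ∈ [−10, 10]`
(tolerance 1e-6); `h² = λ/(1+λ)`. A flat profile (e.g. identity GRM) or an
optimum at the search boundary raises a `boundary` flag rather than failing.
Covariates (generation and regime indicators by default in the pipeline) are
always profiled out; negative eigenvalues beyond −1e-6 of the spectral
radius are rejected as non-PSD.

**Known attenuation in the pipeline estimate.** On the full selection-design
panel the GREML estimate is substantially below the simulated trait h², for
three stacked reasons, verified by ablation during development: (i) the
plot-year residualization removes between-plot genetic differences that
selection created in generation 1; (ii) selection reduces within-plot
genetic variance in generation 1 (Bulmer-type effect, drastic when few QTL
segregate); (iii) the ~2x GBS layer plus mean imputation adds large genotype
measurement error that attenuates the GRM. On generation-0 plants with
perfectly observed genotypes the estimator recovers the simulated value
(test suite, criterion-style recovery checks at n = 768, m = 5000).

## Association scan (`gwas`)

`glm_scan` fits, per marker, OLS of the residual on (intercept, covariates,
current pseudo-QTNs, marker dosage) and reports the two-sided *t*-test on
the marker coefficient. Covariates are projected out once
(Frisch-Waugh-Lovell), making the scan a single pass of matrix products;
agreement with a full per-marker OLS and with a likelihood-ratio test is
asserted in the tests. Markers numerically collinear with the covariates get
p = 1 and a flag.

The pseudo-QTN loop is a deliberately simplified stand-in for published
iterative fixed/random-effect multi-locus scans, whose exact internals are
not replicated: each round, markers with p below the entry threshold are
sorted by p, greedily pruned so no two lie within `min_qtn_distance`
(default 1 Mb), retained if adding them lowers the BIC of the joint
fixed-effect model, and carried as covariates into the next scan; a marker
in the set is tested by temporarily removing itself. The entry threshold
defaults to the significance threshold (1e-5): BIC alone (penalty ≈ log n)
admits markers at p ≈ 0.01 and would let spurious pseudo-QTNs through on a
null genome. Iteration stops when the set stabilizes (or `max_iter`, then
flagged).

Significance is the fixed per-marker threshold p < 1e-5, with no further
multiple-testing correction — at ~300k markers this implies ≈3 expected
false positives genome-wide, which is the design rationale for the value.
QQ data pair sorted observed −log10 p with uniform-order expectations; the
genomic inflation factor is `median(χ²(p)) / median(χ²_1)` with the exact
χ²₁ median (≈0.4549).

## Bulk segregant analysis (`bsa`)

Bulk reference-allele frequencies are computed over non-missing calls of the
bulk members; the pooled two-proportion Z and its two-sided normal p follow
the standard form (no continuity correction; pooled variance). Pooled
monomorphic markers get Z = 0, p = 1; markers uninformative in either bulk
are dropped and logged.

Order of operations where the procedure is ambiguous: the 0.5% outlier
threshold is computed on the **raw** −log10 p values; run detection uses the
**smoothed** values (centered 15-marker mean, truncated at chromosome edges,
never crossing chromosomes); a region must contain at least one **raw**
outlier. This keeps "significant markers" (raw outliers) and "regions"
(smoothed runs) as distinct counts. Runs separated by fewer than 15
sub-threshold markers merge (no merge rule is standard; the parameter is
exposed). The region peak is the marker with the smallest raw p, leftmost on
ties; region length is (right − left)/1000 kb.

**Calibration caveats.** (1) The two-sided Z on integer allele counts has a
probability atom at p = 1 (exactly tied counts, ~2% of markers at
384-individual fully-observed bulks), so its p-values are not literally
KS-uniform even under a perfect null; the tests assert that the deviation
from uniformity equals the tie atom and that the 5% rejection rate is
nominal. (2) Through the ~2x GBS layer the test is anti-conservative: the
binomial variance model understates the variance contributed by miscalled
heterozygotes. This affects any BSA computed on low-depth in-silico bulks
with a binomial sampling model, and is one reason the empirical outlier
threshold (a genome-wide quantile, self-calibrating) is used instead of a
fixed p cutoff.

## Corroboration (`corroborate`)

A significant SNP overlaps a region iff they share a chromosome label and
`left ≤ pos ≤ right`, boundaries inclusive on both ends. Disjoint chromosome
label sets between the two inputs raise an error (coordinate-convention
mismatch). Gene annotation reports every gene whose *span* intersects
±150 kb around the SNP (span intersection chosen over distance-to-start,
which the looser phrase "within 150 kb" leaves open); distance 0 and the
label "SNP in candidate" when the SNP lies inside the gene body. Malformed
GFF3 lines (not 9 tab-separated fields, or inverted coordinates) are skipped
with a warning. Screening candidates by annotation text is out of scope.

## Pipeline (`workflow`) and problem sizes

`run_pipeline` chains simulate/load → filter → standardize → GRM + h² →
pseudo-QTN GWAS → BSA → overlap, writing each stage's table plus a JSON
summary; a stage failure aborts with the stage name. GWAS runs on imputed
dosages; BSA runs on unimputed filtered calls (frequencies must come from
observed alleles only). All thresholds (1e-5, 0.5%, 15-SNP window, MAF 0.05,
40 reads, 150 kb, 5% truncation, ~2x depth) live in the config with the
field-design values as defaults.

The verification scenarios use scaled-down sizes chosen, before any results
were inspected, from power analysis: null calibration at n = 768 and
m = 10,000; heritability recovery at n = 768 / m = 5000 (GREML, mean of 3
replicates since the single-replicate sampling sd of ĥ² at this n/m is
~0.1) and 20 replicates of 5000-plant single-plot truncation experiments
(breeder's equation); end-to-end co-localization on 4 plots × 2000 plants,
600 markers on 3 chromosomes, two +8 cm QTL restricted to founder
frequencies [0.3, 0.7] at target h² 0.8 — effects large enough that the
expected selection-induced frequency contrast between bulks (≳0.3) clears
the 0.5% outlier threshold after 15-SNP smoothing despite
linkage-equilibrium founders.

## Known limitations

- No haplotype-aware imputation or genotype-likelihood model; mean
  imputation biases individual genotypes toward the frequency and
  contributes to GRM attenuation at low depth.
- The pseudo-QTN loop is a structural analogue, not a reimplementation, of
  published multi-locus scans; no per-marker mixed model with the full GRM
  is provided.
- BSA is in-silico only (individual genotypes pooled computationally); no
  read-pool sequencing model, G statistic, or allele-frequency-index
  alternatives.
- The simulator's linkage-equilibrium founders understate region widths
  (see above); its truth record, not Mb-scale block structure, is the basis
  of the end-to-end tests.
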
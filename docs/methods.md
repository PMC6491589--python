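# Methods

This note documents the statistical model, the defaults and the design
choices behind `adprquant`, in the order the pipeline applies them.

## Protein-level filtering

Rows of `proteinGroups.txt` are dropped, in order, when they are flagged as
potential contaminants, reverse-database hits, or identified only by a
modification site; when they have fewer than 2 peptides; or when any
declared reporter channel in any replicate has a non-positive intensity.
Each protein is tallied once, under the first rule that removes it, so the
`FilterReport` counters always sum to input minus kept. The peptide
threshold reads the MaxQuant `Peptides` column by default; "less than two
peptides" could also be read against `Razor + unique peptides`, so the
column is configurable through `ColumnDialect.peptide_column`. Requiring
strictly positive intensities everywhere means no imputation is ever
needed; `log2_per_million` accepts an optional prior count for robustness
but defaults to 0.

Protein groups are keyed by the first accession in `Protein IDs` and never
split. Known-target annotation strips isoform suffixes (`P09874-2` →
`P09874`) on both sides before set membership.

## Normalization

TMM scaling factors follow the trimmed-mean-of-M-values definition: against
a reference column (auto-selected as the column whose upper quartile of
library-size-scaled intensities is closest to the mean upper quartile),
per-protein log2 ratios M and average log2 abundances A are doubly trimmed
— 30% from each tail of M, 5% from each tail of A, rank-based — and the
surviving M values are averaged with inverse delta-method variance weights
`(N_k − y_k)/(N_k y_k) + (N_r − y_r)/(N_r y_r)`. Factors are rescaled to
geometric mean 1. The implementation is cross-checked in the test suite
against both a brute-force reimplementation and edgeR's
`calcNormFactors(method="TMM")`, which it matches to ~1e-15.

Normalization runs jointly across all replicates' columns of an experiment
(matching the requirement of positive intensities "across all reporters and
replicates"); per-plex normalization can be had by passing column subsets.
For the inhibitor experiment the intermediate-dose channels participate in
normalization and debiasing — they occupy TMT channels and contribute to
library sizes — and are excluded only at the design-matrix stage.

The log2-per-million transform is `log2(1e6 · y / (library size × factor))`.

## Design matrices

Cofactor run (TMT6plex, 2 cofactors × {1, 0.5, 0.25} mM × R replicates):
intercept; sum-coded cofactor (+1 = 2YnAd, −1 = 6YnAd, so positive
coefficients mean 2YnAd preference); the natural log of the feeding
concentration in mM (the log base only rescales the coefficient and leaves
its t-statistic unchanged — documented here because the choice is
otherwise invisible); and 0/1 replicate dummies with the first replicate
absorbed into the intercept.

Inhibitor run (TMT10plex, reporters ordered Olaparib 25, 5, 1, 0.2, 0 µM
then Rucaparib 25, 5, 1, 0.2, 0 µM): rows are restricted to the 0 µM and
25 µM channels (reporters 0, 4, 5, 9 of each replicate) so the intermediate
doses do not over-fit a two-parameter response; coefficients are intercept,
inhibitor preference (−1 = Olaparib, +1 = Rucaparib, 0 = no inhibitor),
an inhibition indicator (1 wherever inhibitor is present), and replicate
dummies. A layout without 0 µM channels makes the inhibition effect
unidentifiable and is rejected up front.

`validate_design` reports rank, condition number and aliased columns (via a
greedy least-squares span check) and refuses rank-deficient designs.

The replicate count is a layout parameter with default 2; the
channel-to-condition assignment always comes from the layout/config, never
from hard-coded reporter positions.

## Linear models and empirical-Bayes moderation

Each protein is fitted by OLS against the shared design; residual variance
s²g has dg = n − p degrees of freedom (identical across proteins). The
variance prior is the scaled-inverse-χ² hierarchy: writing zg = log s²g,
E[zg] = log σ²g + ψ(dg/2) − log(dg/2) and the excess of Var(zg) over the
χ² sampling floor ψ′(dg/2) equals ψ′(d₀/2). The location of z (after the
digamma correction) is a lowess curve in average log2 intensity Ag when the
trend is on (span 0.5 by default, configurable) or the mean when off; the
excess dispersion of the residuals is inverted through the trigamma
function (Newton iteration from the 1/x seed, tolerance 1e-8, max 50
iterations) to give d₀, and the back-transformed location gives s₀²(Ag).
Non-positive excess dispersion yields d₀ = +∞ (no moderation needed, the
prior location is used as-is). Perfect fits (s²g = 0) participate with zg
floored at log(machine epsilon × mean variance). Posterior variances are
the convex combination s̃²g = (d₀ s₀²(Ag) + dg s²g)/(d₀ + dg).

Moderated t = β̂ / (s̃g √vj) is referred to Student's t on d₀ + dg degrees
of freedom, normal when d₀ = ∞; tests are two-sided (effects are reported
signed on the volcano, implying a two-sided alternative). The no-trend path
matches limma's `eBayes` to ~1e-8 in the test suite; the trend path uses
lowess where limma uses a spline, so the two agree closely but not
bitwise — the lowess choice keeps the estimator local and assumption-free
about the trend's shape.

Benjamini–Hochberg adjustment (via `statsmodels.stats.multitest`) is
applied per coefficient across proteins — never pooled across the two
tested coefficients of the inhibitor model, which are tested separately.
Significance is the strict comparison adjusted p < α, default α = 0.01.

## Debiasing and descriptive exports

For plotting, the fitted intercept and replicate-bias contributions are
subtracted exactly: `Y − X_bias β̂_bias`. Because those roles depend only on
the replicate, the subtraction extends to observations outside the fitted
design (the intermediate inhibitor doses). Refitting after debiasing
reproduces every tested effect to 1e-10 and drives the nuisance
coefficients to zero; debiasing is idempotent. The inhibitor response
scatter is the per-inhibitor mean of debiased 25 µM values minus the mean
of debiased 0 µM values (the control channels are shared between
inhibitors); since the subtraction is exact, averaging before or after
debiasing is equivalent. Dose–response profiles are replicate-averaged
debiased log2 intensities per (inhibitor, concentration), over all five
doses. Volcano records carry the signed effect and −log10 adjusted p,
capped at 16 (configurable) for p = 0. Plot-ready TSVs are the canonical
artifacts; figure rendering is left to the consumer.

## Synthetic experiments

The generator draws protein baselines log2-normal (mean 7.5, sd 2.0 on the
log2-per-million-like scale), applies the relevant design's effects
additively on the log2 scale, adds Gaussian noise with per-protein
variances from scaled-inverse-χ²(d₀ = 4, s₀² = 0.05) (optionally an
intensity-dependent scale), exponentiates, and rescales columns so the
clean proteins hit library sizes drawn uniformly from 5e8–1.5e9 — typical
TMT reporter column totals. Generating on the log2 scale and exponentiating
makes the analysis model exactly the generative model, deliberately: the
end-to-end tests are sharp parameter-recovery tests, not robustness
studies. Consequences for interpretation: passing tests demonstrate
correctness of the estimators under the assumed model; they do not speak to
reporter-ion ratio compression, isotope-impurity cross-talk,
peptide-to-protein rollup, or missingness mechanisms, none of which are
simulated.

Default study conditions: 10% responsive proteins with effect magnitudes
|N(1.0, 0.25)| log2 units and random sign; every protein gets a
concentration slope N(0.3, 0.1) log2 per ln(mM) in the cofactor design
(labelling scales with probe feeding concentration for all labelled
proteins, so the slope is population-wide while the preference is not);
responsive proteins in the inhibitor design additionally get an inhibition
effect N(−1.0, 0.25). Replicate offsets default to +0.3 log2 per replicate
after the first. Intermediate doses are ramped by a saturating curve
`log1p(c/1 µM)/log1p(25/1)` that is 0 at the control and exactly 1 at
25 µM, so the top-dose channels carry exactly the design-encoded effects.
Decoy rows (20 contaminants, 10 reverse, 10 site-only, 15 single-peptide,
10 with one injected zero) exercise every filter rule; clean peptide counts
are uniform 2–40 and single-peptide decoys get exactly 1. Everything is
reproducible from one integer seed.

## Numerical and testing choices

* Observation order is always replicate-major, channel-minor; reporter
  matrices carry (replicate, channel) column keys and design rows align by
  key, so column order can never silently rotate.
* Library-size rescaling in the generator adds per-column constants outside
  the design span. TMM plus log2-per-million removes them up to a small
  estimation error; the structural tests therefore check coefficient
  recovery up to a shift that must be identical across proteins.
* Null calibration is assessed per simulated experiment with a KS test at
  level 0.01 over 20 seeded replicates, allowing at most 2 failures (the
  binomial allowance at that level), plus the BH significant-fraction bound
  of 2%.
* The pooled-variance moment check of the generator uses d₀ = 6 because the
  second moment of the scaled-inverse-χ² is finite only for d₀ > 4; at the
  default d₀ = 4 the mean exists but its estimator is heavy-tailed.
* Acceptance-script problem sizes: 5000 proteins per experiment and 5 null
  runs, the same scale as the test suite's property checks.

## Known limitations

* Robust variance moderation (outlier-variance protection), observation
  weights and within-plex correlation modelling are not implemented.
* The trend estimator needs a few hundred proteins to be stable; a warning
  fires below 50.
* Peptide-level tables (`evidence.txt`, `msms.txt`), protein inference and
  PSM-level FDR are out of scope — the pipeline starts from protein groups.
* Pathway enrichment and site localisation are out of scope.
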
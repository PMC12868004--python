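# Methods

This note records the statistical model, the numerical conventions and the
design choices behind `brainprot`, in the spirit of a package's model
documentation: enough detail that every computed number can be re-derived.

## Input model and normalization

The pipeline starts from a quantified protein × sample matrix of linear
intensities with missing values, plus a sample → (donor, region)
annotation. Raw zeros are treated as non-detections and coerced to missing
at read time: DIA label-free zeros denote signals below the detection
limit, and a measured zero would map to −∞ under log2. On-disk missing
values are an empty cell or the literal `NA`, nothing else.

Each sample is scaled so its **observed** intensities sum to 10⁶ (ppm);
the denominator deliberately excludes missing proteins because the
observed total is the only total available under missingness. No
pseudocount and no imputation are applied anywhere — missing values
propagate, and each downstream statistic declares its own complete-data
requirement (the ANOVA needs ≥ 3 observed regions and ≥ 1 residual df; the
PCA is complete-case; CVs need ≥ 2 observations). ppm values are log2
transformed for all location statistics. CVs are computed on the linear
ppm scale, where a coefficient of variation is conventionally defined.

## Donor-blocked region ANOVA

Samples from one donor share unmodeled biology, so they are not
independent across regions. The model per protein is a fixed region effect
plus a donor random effect with variance σ_d² and residual variance σ_e²,
giving a compound-symmetry intra-donor correlation ρ = σ_d²/(σ_d²+σ_e²).

**Consensus correlation.** A single ρ is pooled across proteins, analogous
in role to limma's `duplicateCorrelation`, but re-derived as a closed-form
method-of-moments estimator:

1. residuals e are taken about fitted region means;
2. within-donor cross-products e_a·e_b are summed over pairs of samples in
   *distinct* regions (same-region pairs would mix residual covariance in);
3. the sum is divided by γ_g, the exact expectation coefficient of those
   cross-products under compound symmetry. For a pair in regions r, r' of
   one donor, γ_pair = 1 − 1/n_r − 1/n_r' + Σ_l c_{lr} c_{lr'}, with
   c_{lr} donor l's share of region r's observed samples. Residuals about
   fitted means attenuate cross-products by roughly (1 − 1/n_region); γ
   undoes exactly that, for an arbitrary observed donor × region incidence
   pattern;
4. the ratio to the residual variance s² (df = n_obs − regions observed,
   required ≥ 3) gives ρ̂_g, clamped to [−0.95, 0.95];
5. per-protein estimates are Fisher-z transformed, trimmed-mean averaged
   (0.15 from each tail, robust to outlier proteins) and transformed back;
6. because only ~8 donors inform each protein, any correlation-type ratio
   carries an O(1/n_donors) downward bias (≈ −0.03 at ρ = 0.5 here). The
   reported consensus is therefore the delete-one-donor jackknife of the
   pooled estimate, D·ρ̂_all − (D−1)·mean_j ρ̂_(−j), which removes the
   first-order bias; with too few donors for leave-one-out the plain pool
   is returned.

Proteins whose residuals are identically zero, or with no usable
within-donor pairs, contribute nothing (`n_used` reports the pool size).

**Whitening and F-test.** Each donor block of m observed samples is
whitened with the closed-form inverse square root of the compound-symmetry
matrix, y* = (y − c·ȳ_block)/√(1−ρ) with
c = 1 − √((1−ρ)/(1+(m−1)ρ)); a one-way region ANOVA then runs on y* with
df1 = regions_observed − 1 and df2 = n_obs − regions_observed (blocking
enters only through the covariance, so no df are spent on donor means). At
ρ = 0 this reduces bit-for-bit to the textbook one-way ANOVA, which the
tests verify against an independent oracle. ρ outside
(−1/(m_max−1), 1) leaves the covariance non-positive-definite and is an
error. Degenerate proteins: SSB ≈ 0 (relative to total SS, tolerance
1e−12) gives F = 0, p = 1; SSW ≈ 0 with SSB > 0 gives F = ∞, p = 0.

**Calling rule.** p-values of testable proteins are Benjamini–Hochberg
adjusted (direct step-up, adj_(i) = min_{j≥i} p_(j)·m/j capped at 1,
missing entries preserved). The fold change compares the highest-mean
region with the mean over all observed samples pooled from the remaining
regions; on the default log2 scale it is the geometric-mean ratio
2^(Δ mean log2) (an arithmetic linear-scale variant is exposed via
`fc_scale="linear"`). Ties for the top region are broken by the fixed
region declaration order and flagged. A call requires: testable (≥ 3
observed regions, df2 ≥ 1), p_adj < 0.01, fold change ≥ 1.5 (non-strict —
ties at the threshold are measure-zero), and ≥ 2 observations in the top
region. The testability and min-observation gates are this package's
conventions for missing data; nothing weaker would make the top-region
mean meaningful.

The four-lobe shared signature generalizes the rule: a protein belongs
when each of FL, TL, PL, OL individually exceeds the pooled noncortical
mean by the fold-change threshold and the overall p_adj passes. The
criterion behind the published four-lobe set is not fully specified
anywhere; this definition is the package's documented stand-in.

## Abundance quartiles

Within each region, the mean ppm per protein over observed samples is
normalized to fractions summing to 1; proteins are sorted descending (ties
by protein id for reproducibility) and each protein is binned by the
*start* of its cumulative interval into [0, .25), [.25, .5), [.5, .75),
[.75, 1). The start-of-interval rule decides proteins straddling a cut;
the dominance invariant (every Q1 fraction ≥ every Q4 fraction) and the
partition property are enforced by tests.

## Region modules

Regions are summarized by mean log2-ppm profiles; Pearson correlations are
pairwise-complete over shared proteins, with the pair counts reported so
the choice is auditable. Complete-linkage agglomeration on d = 1 − r is
implemented in-package (13 leaves) so the tie rule — smallest cluster
index pair on equal minimum distances, tolerance 1e−12 — is deterministic
and documented; tests verify agreement with scipy's implementation and a
brute-force merge enumeration. The expected groups at the k = 4 cut are
the three observed clusters: {FL, TL, PL, OL}, {HIP, AN}, {THA/HT, CC,
VT}. The wider three-module view of brain organization additionally places
THA/HT in the limbic-relay network and OC on the midline axis; a
dendrogram cut cannot express overlapping membership, so those constants
are kept separate from the clustering output.

## Cross-omics concordance

RNA specificity follows the stated rule literally: nTPM < 1 → missing,
log2 of the rest, specific iff max log2 ≥ 2 × mean log2 of the remaining
non-missing regions (a ratio of log values, not a fold change; the
boundary is non-strict). When the remaining mean is 0 — all remaining
regions at the floor or none expressed — the limit convention applies:
specific iff max log2 > 0. Protein calls are translated to the coarser RNA
vocabulary (FL/TL/PL/OL/OB_OT → Cx; CB, BS, HIP, THA_HT map to themselves;
OC, CC, VT, AN have no RNA counterpart). Classes partition the protein
universe: `unmapped` (no gene), `both`, `protein_only`, `rna_only`,
`background`; `both` does not require region agreement, which is reported
as a separate flag.

## Synthetic data generator

The generator emulates the study conditions: 13 regions × 8 donors, one
sample per donor-region cell with 5 cells dropped at random (99 samples of
104 — the published design is unbalanced but its per-region coverage is
not reported, so the dropout mechanism is a modeling choice), 4,660
proteins by default. Log2 signal: baseline μ_g ~ N(7.5, 2.0²) on the
log2-ppm scale (≈ 4–5 orders of magnitude dynamic range), a planted marker
elevation (default 50 markers/region at log2 effect 2, matching the
recovery benchmark), a donor effect drawn independently per protein
(σ_d = 0.3) and residual noise (σ_e = 0.5), so ρ_true ≈ 0.265 by default.
Raw value = 2^signal × a log-normal per-sample depth factor (sd 0.25) that
the ppm normalization must cancel. With `region_groups` set, markers are
shared by every region of a group — the block-structured design used for
module recovery.

Missingness is MCAR (rate 0.10) followed by left-censoring MNAR with
probability logistic((mid − signal)/scale). The published completeness
statistic is a *median* missing rate of 16%, and MNAR skews the
protein-level distribution, so one parameter set cannot put both the
median and the overall rate at 16%: the defaults (mid 4.8, scale 1.0,
derived analytically from the normal signal model) target the median
statistic (measured ≈ 17% at the defaults, with an overall cell rate
≈ 24%), while the recovery benchmarks use mid 3.5 to put the *overall*
rate at ≈ 16%. The matched RNA table gives every protein a gene
(`g_<protein>`) minus a 10% unmapped fraction; a marker whose home region
has an RNA counterpart is made RNA-specific with probability
`rna_concordance` (default 0.5, reflecting the modest protein–RNA
agreement of brain surveys) using an nTPM pattern (32 vs 2) that passes
the RNA rule; all other genes get flat profiles that fail it.

What the generator does **not** emulate: peptide-level structure,
correlated missingness across proteins, batch effects beyond a scalar
depth factor, heteroscedastic per-protein variances, or real biological
covariance between proteins. Passing recovery benchmarks therefore
demonstrates the statistics are correct and calibrated under the stated
model, not that real data meet the model's assumptions.

## Benchmarks and problem sizes

The frozen scenarios in `brainprot.evaluate` (used by both the test suite
and `scripts/acceptance.py`): marker recovery at 5,000 proteins ×
50 markers/region (sensitivity ≥ 0.90, empirical FDR ≤ 0.05 pooled across
regions, region accuracy ≥ 0.95 expected); correlation recovery at 2,000
proteins (ρ = 0 and 0.5, ±0.05); null calibration over 5 × 2,000-protein
replicates (mean called fraction ≤ α); module recovery over 20 seeds of
1,000-protein block-structured datasets (baseline sd 1.5 there, so the
shared-marker covariance is not swamped by the baseline spread). These
sizes keep a full run in seconds while leaving the Monte Carlo error well
inside the stated bands. Replicate seeds derive deterministically from the
master seed (seed + index); all randomness flows through
`numpy.random.default_rng`.

## Numerical conventions

TSVs are written with 12 significant digits (`%.12g`), which round-trips
the analysis output and makes reruns byte-identical; missing is `NA`.
Region tokens `THA_HT` and `OB_OT` stand for the anatomical labels THA/HT
and OB/OT, which are accepted as input aliases. Known limitations: the
consensus-correlation jackknife assumes donors are exchangeable; the
calling rule treats region effects as the only fixed effects (no
covariates such as age or postmortem interval); and `both`-class
concordance depends on the supplied protein→gene map, whose isoform
handling is the caller's responsibility.
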
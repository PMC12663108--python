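# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated on — including what the simulations do and
do not establish about real data.

## Exposure: CW-D-UVB

The cumulative weighted ambient UVB dose for a participant sampled on
date t at grid cell c is

    CW-D-UVB = Σ_{x=1..W} D_c(t − x) · exp(−(ln 2 / h) · x)

with half-life h = 35 days and window W = 135 days; x = 1 is the day
before blood draw, and the sampling day itself is excluded. The window
length reflects that contributions decay to < 7% of their initial weight
by day 135; both parameters are overridable.

Daily doses live on a lower-left-anchored, half-open lat/lon grid
(default quarter-degree cells). A point exactly on an interior boundary
belongs to the higher-index cell; the cell's single stored value is used
without spatial interpolation, since the source data are already
cell averages. Missing days inside the window are linearly interpolated
between the nearest observed neighbours; runs touching a window edge
carry the nearest value; more than 10% missing aborts that participant
with a per-record error that leaves the rest of the cohort unaffected.

British National Grid easting/northing are inverted with the standard
transverse-Mercator series on the Airy 1830 ellipsoid (scale
0.9996012717, true origin 49°N 2°W, false origin 400 000, −100 000 m).
The meridional-arc iteration stops at 1e-9 m — the arc is O(1e6) m, so
this is at the resolution limit of double precision — and round-trips
against an independent forward projection to < 1e-6°. No OSGB36→WGS84
datum shift is applied by default: the ~100 m discrepancy is three
orders of magnitude below a quarter-degree cell. A 7-parameter Helmert
transformation is available behind a flag for datum-consistent output.

## Quality control

Variant filters apply in the order imputation-info → missingness → MAF →
Hardy–Weinberg (each variant is recorded under the first filter it
fails); defaults: info ≥ 0.8, missingness ≤ 0.02, MAF ≥ 0.01, HWE
p ≥ 1e-6. Sample filters: missingness ≤ 0.02, heterozygosity within ±6
SD of the cohort mean, then greedy kinship pruning at the KING-robust
threshold 0.0884 (second-degree relatives or closer); of each flagged
pair the member with higher missingness is dropped, ties to the later
sample. Sample QC precedes variant QC, and the whole procedure is
idempotent.

The HWE test is the exact conditional test: with the minor-allele count
fixed, P(h heterozygotes) ∝ n!/(n_AA! h! n_aa!)·2^h, and the p-value
sums all configurations no more probable than the observed one
(standard, not mid-p). Computed in log-space; verified against integer
enumeration for every genotype triple with n ≤ 50.

Hard calls for HWE, heterozygosity, and kinship come from rounding
dosages, with dosages in (0.1, 0.9) ∪ (1.1, 1.9) treated as missing — an
imputation-uncertainty guard. KING-robust between-family kinship is
φ̂ = N_{Aa,Aa}/(2N_min) + 1/2 − (N^i_Aa + N^j_Aa)/(4N_min) − 2N_{AA,aa}/(2N_min),
N_min the smaller heterozygote count. Its sampling noise scales as
~1/√m, so pairwise screens need a few thousand shared hard-called sites
before the 0.0884 threshold separates cleanly from noise (the analysis
bundle uses 5000 variants for 500 samples for exactly this reason); a
configurable minimum of shared sites (default 100) guards degenerate
calls.

## Association engine

The phenotype is clamped at the assay detection limit (10 nmol/L),
natural-log transformed, and z-scored against the analysis sample;
strata re-standardize internally. Missing dosages are mean-imputed per
variant, keeping n constant across variants.

Per variant, two least-squares fits (marginal; interaction with a G×E
column) yield the three tests. Both σ²(XᵀX)⁻¹ (σ² = RSS/(n−p)) and the
HC0 sandwich covariance are stored. The marginal test always uses the
model-based SE, as an ordinary GWAS does; the 1-df interaction and 2-df
joint Wald tests use the sandwich by default (switchable) — an
interaction on a transformed scale is precisely the mean–variance
misspecification the sandwich is robust to, and at the sample sizes
involved the small-sample corrections (HC1–HC3) are immaterial.

`run_gweis` residualizes y and the per-variant [G, G×E] columns against
the shared covariates once (QR-based Frisch–Waugh–Lovell) and solves a
2×2 system per variant, vectorized in chunks. This is algebraically the
full-design fit — including the sandwich block — and the tests assert
agreement with a naive normal-equations oracle and with independent OLS
implementations to 1e-8. Constant-dosage variants are emitted as skip
records; rank-deficient covariate designs raise an error naming the
collinear columns.

Exposure quintiles use rank-based assignment with stable tie-breaking,
making labels deterministic and invariant under monotone transforms. BMI
categories follow the 18.5/25/30 kg/m² cutoffs.

## Variant selection, replication, risk scores

Clumping: sort significant variants by (p, chromosome, position); take
the best remaining as lead, discard the remainder with r² ≥ 0.1 to it
(squared dosage correlation in the supplied LD source). Stepwise
conditional selection runs on individual-level data — exact conditional
fits rather than a summary-statistic approximation: forward-add the
candidate with the smallest conditional p (marginal model with all
selected variants within a 10 Mb window as covariates) while p < 5e-8,
backward-drop any selected variant whose joint p rises above the
threshold (dropped variants stay out, guaranteeing termination), and
skip candidates with r² > 0.9 to a selected variant.

Sign concordance between discovery and replication effects uses the
exact two-sided binomial test at p₀ = 1/2, excluding exact-zero
estimates, alongside the Pearson correlation of the paired estimates.
Variance explained on a standardized trait is 2β²f(1−f) per variant;
for independent causal loci the sum matches the joint-fit empirical R².
Risk scores are Σ_j dosage_ij·β_marginal_j and
Σ_j dosage_ij·(β_G_j + E_i·β_GxE_j), each replication participant using
their own exposure; evaluation regresses raw 25OHD on score + age + sex
and reports the slope (nmol/L per unit) and the top-vs-bottom score
decile contrast.

## LD score regression

LD scores are computed in-sample from the analysis genotypes (no
external reference): ℓ_j sums the bias-adjusted squared correlations
r̃² = r² − (1−r²)/(n−2) over same-chromosome neighbours within a
window of 200 variants either side, self term included. Univariate LDSC
regresses χ² on ℓ under E[χ²_j] = 1 + a + (N·h²/M)·ℓ_j with a free
intercept, heteroskedasticity weights 1/max(ℓ,1), and one re-weighting
pass using the first-pass predicted means; SEs come from a delete-one
block jackknife over 20 contiguous variant blocks. Bivariate LDSC
regresses z₁z₂ on ℓ for the genetic covariance and forms
r_g = gcov/√(h₁²h₂²), jackknifing the ratio on shared blocks. With an
in-sample panel the intercept legitimately sits slightly above 1 (the
GWAS χ² pick up in-sample correlation noise with all causal variants,
≈ h²·m/n); the free intercept absorbs this.

A generalized-least-squares variant using the banded χ² covariance
implied by local LD was evaluated and gave no variance reduction over
the weighted fit, so the simpler weighting is retained.

## Synthetic data

Genotypes: per haplotype, a latent standard-normal AR(1) series within
LD blocks (block size 20 by default), thresholded at the
allele-frequency quantile; dosage is the sum of two independent
haplotypes, so HWE holds by construction. The per-block autocorrelation
is drawn per block from a range (default 0–0.95): real genomes have
strongly heterogeneous LD, and that heterogeneity is what gives LD
scores the spread LD score regression needs — with a single common ρ
the χ²-on-ℓ slope is barely identified. Each block has its own spawned
random stream, as does every other component (exposure grid, residences,
effects, covariates, noise), from a fixed-position registry, so adding
variants or components never perturbs earlier draws and identical
configurations are byte-reproducible.

Ambient UVB: clear-sky daily dose = 8.484·max(sin e_noon, 0)^3.284
kJ/m², where e_noon is the noon solar elevation from latitude and day
of year. The two constants calibrate the June and December monthly
means at 51.5°N to 5.56 and 0.11 kJ/m² — the observed ~50-fold London
seasonal contrast; amplitude and annual mean fall with latitude
automatically. Day-to-day cloudiness multiplies each cell/day by an
independent mean-1 lognormal factor (σ_log = 0.4).

Cohorts: a standardized latent phenotype z = Σβ_G g̃ + γE_std +
Σβ_GxE g̃E_std + covariate terms + ε, with effects rescaled so realized
variance shares hit their targets; raw 25OHD = exp(3.85 + 0.5z) clamped
at 10 nmol/L (median ≈ 47 nmol/L, right-skewed). Architectures:
`additive` (no interactions), `interaction` (locus-specific β_GxE on a
random causal subset), `amplification` (β_GxE ≡ κ·β_G genome-wide, i.e.
effect sizes scale with the environment). Defaults: h² share 0.10,
exposure share 0.12, interaction share 0.05, small age/sex/supplement
effects; BMI is simulated independent of the phenotype (the stratified
analyses take BMI labels as given precisely to avoid building a
collider into the generator).

Under the `interaction` architecture the generative model coincides
exactly with the estimation model, so parameter recovery is well-posed.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency/LD coupling, population structure (the PCs are pure
noise covariates), imputation error beyond an info-score column,
X-chromosome dosage coding, and assortative or family structure beyond
the planted QC failures. Passing recovery tests therefore demonstrates
the correctness of the estimators under their assumed models, not
robustness to those real-data complications.

## Study conditions and experiment design

The validation experiments fix desk-scale conditions chosen for
well-posedness, not reproduction of any cohort-specific value:

- Type-I error and genomic-inflation checks use 2000 null variants in
  linkage equilibrium at n = 2000: the exact binomial band and the
  λ ∈ [0.95, 1.05] band are bands for *independent* tests; under block
  LD the effective test count drops ~10-fold and the median χ²
  fluctuates well outside them under a perfect null.
- Power ordering uses 200 replicates of a pure-interaction variant
  (MAF 0.3, β_GxE = 0.07, n = 2000) at α = 0.05.
- Heritability recovery: 10 replicates at n = 5000, m = 2000 of a
  *purely genetic* polygenic trait (all variants causal, no exposure or
  covariate effects — otherwise the scan estimates the heritability of
  the covariate-adjusted phenotype, h²/(1 − non-genetic share), and the
  target is misdefined), with LD blocks of 10 so the regression and the
  20-block jackknife rest on 200 independent LD units.
- Genetic correlation: r_g = 0.5 between two strongly heritable traits
  (h² = 0.5, n = 5000, m = 3000) scanned on one panel; sample overlap
  loads only the free gcov intercept. Weak heritability makes the ratio
  gcov/√(h₁²h₂²) unstable at these sizes.
- The heritability gradient runs 10 replicates of amplification with
  κ = 0.5 against an additive control, n = 5000, m = 2000, quintile
  strata of 1000.

## Known limitations

- LD scores are in-sample; reading external reference score files is
  not supported.
- HC0 only (no small-sample sandwich corrections); fine at GWAS n, not
  for small cohorts.
- The kinship screen is O(n²) pairs and meant for cohort-scale QC at
  desk sizes, not biobank scale.
- Stepwise selection requires individual-level data by design; there is
  no summary-statistic + external-LD mode.
- Single-threaded throughout; the fast path is BLAS-bound.
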
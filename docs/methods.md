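# Methods

`millet-nirs` re-implements, as a tested pipeline on synthetic data, a
near-infrared (NIR) calibration workflow for fat and protein content in
foxtail millet kernels: spectral preprocessing, stability-screened
wavelength selection by a binary sparrow search algorithm (SSA),
calibration model construction (PLS, random forest, SVR) and
Shapley-value interpretation. The original spectra and wet-chemistry
panels are not publicly deposited, so the package carries a
forward-model simulator that reproduces their documented structure; all
quantitative claims made by the test suite are claims about that
synthetic system.

## Synthetic data model

**Band axis.** The instrument covers 900–1700 nm in 172 bands at
4.715 nm resolution. The absolute wavelength of the first band is not
documented, but the three consecutive printed protein key wavelengths
(992.363, 997.077, 1001.79 nm) are 4.715 nm apart, which pins the grid
phase. We anchor the grid so 992.363 nm is an exact grid point, with the
grid starting 20 spacings below (898.063 nm). This reproduces the
printed protein wavelengths to ≤0.01 nm and yields exactly 148 bands in
the 950–1650 nm modelling interval. The printed *fat* key wavelengths
are not all mutually consistent with a single uniform 4.715 nm grid
(e.g. 1003.51 and 1526.84 nm differ by 110.96 spacings); the grid is
anchored on the protein list and the discrepancy is left as an
instrument-reporting ambiguity.

**Reference contents.** Fat and protein contents are drawn from
skew-normal distributions, moment-matched to mean 3.74 %, SD 0.35 %,
skewness −0.13 (fat) and mean 10.43 %, CV 3.72 % (SD 0.388 %), skewness
−0.41 (protein). The skew-normal was chosen because a plain normal
cannot express the reported (mild) negative skews; moment matching uses
the standard inversion of the skew-normal mean/variance/skewness
formulas. Non-positive draws are redrawn.

**Spectra.** Absorbance is linear in analyte content through Gaussian
absorption bands (decadic Beer–Lambert):

    A_i(λ) = Σ_a c_ia · k_a(λ) + b_i(λ) + ε_iλ,   R_i(λ) = 10^(−A_i(λ)) · s_i

with `k_a(λ)` a sum of Gaussians. Default fat bands sit at the C–H
overtone/combination positions 1048, 1210, 1390 and 1510 nm; protein
bands at the N–H/amide positions 995, 1190, 1270, 1440 and 1650 nm;
both analytes share a band at 1341 nm, emulating the C–H/N–H overlap
region where fat and protein information is collinear. Band widths are
15–30 nm. Amplitudes (absorbance per % content) are sized so that one
analyte SD of content moves absorbance by roughly 0.002–0.01 at band
centres — above the additive noise floor (ε ~ N(0, 0.003)) without
saturating. The nuisance terms are a per-sample multiplicative scatter
factor s_i ~ N(1, 0.02) and a per-sample baseline offset + linear tilt
(amplitude 0.03), i.e. exactly the artefact classes SNV exists to
remove. These levels are fixed defaults of the generator, not tuning
knobs: with them the fat calibration reaches prediction R² ≈ 0.78 and
RPD ≈ 2.2 while protein — whose relative variation is 2.5× smaller —
calibrates substantially worse, reproducing the qualitative asymmetry
expected from the two analytes' dispersion.

What the simulator does **not** model: hyperspectral image formation
(spectra are mean-ROI equivalents), wavelength-dependent instrument
noise, moisture/starch interferents, dark-current drift, and any
non-linearity of the true reflectance–content relationship beyond the
10^(−A) transform. Passing tests therefore demonstrate that the
*pipeline machinery* is correct and recovers planted structure; they do
not certify accuracy figures on real millet spectra.

**Calibration frames.** `make_calibration_frames` wraps true
reflectance T into raw/white/dark frames with R0 = Rb + T·(Rw−Rb), so
the standard two-point calibration R = (R0−Rb)/(Rw−Rb) inverts exactly;
the round trip is tested to 1e−12 relative.

**Wet chemistry.** The Soxhlet fat formula (100·P/m) and Kjeldahl
protein formula (100·(V1−V0)·C·0.014·5.83/m, with 5.83 the millet
nitrogen-to-protein conversion factor) are provided as reference-value
utilities; the bench procedures themselves are out of scope.

## Preprocessing

Savitzky–Golay smoothing runs before SNV (the order used for the
published spectra figures). The S–G window (11) and polynomial order (2)
are not documented in the source protocol; window 11 ≈ 52 nm is a
standard choice for ~150-band NIR spectra and both are exposed in the
configuration. SNV centres and unit-scales each spectrum with the n−1
denominator; it is idempotent to 1e−12.

Outlier screening uses the 1.5×IQR fence per analyte independently — a
sample flagged for protein leaves the protein dataset only. Descriptive
statistics use SD with n−1, CV = 100·SD/mean, *non-excess* kurtosis
(normal = 3; the documented kurtosis values 2.48/3.18 cluster around 3,
not 0) and Student-t 95 % confidence intervals.

The hold-out split draws a seeded uniform permutation with training size
`round-half-up(0.75·n)`; this rounding reproduces the documented
161/53 (n = 214) and 144/48 (n = 192) partitions.

## Wavelength selection

**Search space.** Binary inclusion vectors over the 148 bands,
constrained non-empty (violations repaired by switching on one random
band).

**Fitness.** Mean over seeded 5-fold CV of the fold MSE of a PLS model
on the selected columns, with `min(5, |s|, fold size − 1)` latent
variables. The protocol names no inner regressor for the search itself
but adjudicates candidate sets with 5-fold CV + PLS, so the same engine
is used for both, for coherence; it is exposed in the configuration. The
inner PLS is a minimal NIPALS implementation (`_fastpls`), validated
against scikit-learn to 1e−8 on random matrices, because the search
performs ~10⁵ small fits per run and per-call estimator overhead would
dominate. Fitness values are memoised on the subset bit pattern.

**SSA roles.** Each generation, the population is ranked by fitness:
the top 70 % (discoverers) mutate each bit with probability 0.1,
accepted on strict improvement; the middle 10 % (followers) copy a
random discoverer, flip bits at probability 0.3, accepted on strict
improvement; the worst 20 % (sentinels) are replaced — with probability
0.8 (the safety threshold) by a fresh uniform random subset, otherwise
by the global best mutated at the discoverer rate. The qualitative
descriptions "a certain probability" / "a high probability" for the two
mutation rates are made concrete as 0.1/0.3 and are configurable; the
operative role of the safety threshold in the binary variant is
likewise under-specified in the source protocol, and the
re-initialisation interpretation above is this package's design choice.
Equal-fitness ties keep the incumbent. The global best is tracked each
generation; its fitness trace is non-increasing by construction and
asserted so in tests.

**Stability screening.** R independent runs (seeds seed+0 … seed+R−1,
sharing one fitness cache) yield a per-band selection frequency
(count of best subsets containing the band, over R — runs, not
population visits). Candidate sets come from three strategies: all
bands with frequency > 50 %; top-N by frequency for N = 10…50 step 5
(nine sets, frequency ties broken toward the lower band index); and
frequency levels ≥ 0.5, 0.6, 0.7, 0.8, 0.9, discarding level sets with
fewer than 5 members. Candidates are adjudicated by the same 5-fold CV
PLS error (per-fold RMSEs are averaged for reporting; the MSE mean is
the criterion); ties prefer fewer bands, then the lower first index.

**Scale.** The full protocol is 50 runs × population 100 × 500
iterations. The package's demo configuration, used by the analysis
scripts and the acceptance script, runs 20 × 30 × 100 on 300 samples —
the same machinery at a desk-friendly budget. Both are plain
configuration values.

## Calibration models

PLS selects its latent-variable count by seeded 5-fold CV over
1…min(20, bands, fold size − 1). The random forest uses 100 trees and
minimum leaf size 5 with no explicit depth cap — "depth determined by
the minimum leaf count" is implemented as: splitting stops when a child
would drop below 5 samples. SVR uses an RBF kernel with cost ∈ 10^[−1,3],
width ∈ 10^[−4,1] and ε ∈ [0.01, 0.3] drawn 60 times by seeded random
search, scored by 5-fold CV MSE. Predictors are standardised with
training-set statistics before PLS and SVR (whether the original
workflow standardised is undocumented; standardising is the
conventional default for both families); the forest sees raw values.

Metrics: R² = 1 − SSE/SST; RMSE with the population denominator n
(consistent with the MSE fitness); RPD = SD(reference values of the
evaluated set, n−1)/RMSE — the source states RPD thresholds but no
formula, and this is the standard convention. A perfect fit reports
RPD = +inf. Families are ranked by prediction-set R², ties by lower
prediction RMSE.

Numerical note on the recovery check: the all-families parameter
-recovery test uses a 2-band planted problem. Random forests predict
piecewise constants, so near-perfect R² on a continuous linear target
requires dense coverage of the feature space; at 5 dimensions and a few
hundred samples a forest cannot exceed R² ≈ 0.3 on such a target no
matter how correct the implementation. Low dimensionality is the regime
in which "every family recovers the signal" is a property of the
implementation rather than of the estimator class.

## Shapley interpretation

For PLS (affine in features) the exact closed form is used:
φ_ij = β_j·(x_ij − mean_j(background)), with β probed as
unit-perturbation prediction differences at the background mean, and the
base value the prediction at that mean; additivity is exact. For
black-box models (RF, SVR) an interventional permutation-sampling
estimator is used: feature orderings are sampled (default budget 200),
each paired with one background row taken from a seeded shuffled cycle,
and each ordering is evaluated forward and reversed (antithetic pair),
which empirically cuts the sampling error by an order of magnitude on
near-additive models. The background/reference set is always the
training partition, so prediction-set explanations leak no test
statistics. Additivity holds within 1 % relative at the default budget
and is asserted in tests; exactness on ≤3-feature models is checked
against full coalition enumeration.

The global summary reports the mean signed Shapley value per wavelength
(positive = increases predicted content on average), contribution rates
100·mean|φ_j|/Σ_k mean|φ_k| (sum to 100 %), and the minimal top-k
counts whose cumulative rate reaches 80 % and 95 %. Dependence profiles
pair a wavelength's values with its attributions; |Spearman ρ| ≥ 0.95
flags a monotone profile.

## Reproducibility

Every source of randomness is a `numpy.random.default_rng` seeded from
an explicit parameter. The pipeline derives all stage seeds from one
master seed by fixed offsets and records them in a JSON manifest;
rerunning a configuration reproduces all artifacts bit-identically
(asserted in tests).

## Known limitations

- All accuracy figures are on synthetic data; the generator's band
  positions and noise levels are plausible but not fitted to real
  millet spectra.
- The SSA fitness carries no explicit cardinality penalty, so best
  subsets can stay large when extra bands are harmless to CV error;
  parsimony enters only through the candidate-set strategies and the
  fewer-bands tie-break.
- The permutation Shapley estimator scales linearly in features ×
  permutations × samples and becomes slow beyond ~10⁵ model
  evaluations per explained sample.
- The cropped-band subset after selection is generally non-uniform, so
  derivative-style preprocessing (not used here) would need the explicit
  wavelength axis.
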
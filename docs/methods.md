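# Methods

## Normalization

All modeling operates on structure volumes expressed as percent of the
intracranial cavity volume (ICV): `100 * v / icv`, values in [0, 100].
Normalizing by the per-subject sum of all segmented structures is available
as an option (`denominator="sum_of_structures"`); ICV is the default
because it is the standard head-size correction for volumetry and is
independent of the segmentation's structure list. Sex is carried as
metadata only — neither model uses it as a covariate.

## Average normative model (lifespan baseline)

Per structure, ordinary least-squares polynomial regression of normalized
volume on age. The degree defaults to 2; `degree="auto"` picks 1–3 per
structure by BIC (`n·log(RSS/n) + k·log n`), which on truly linear data
selects degree 1. The normative range at age `a` is
`poly(a) + [q0.05, q0.95]` where the q's are empirical quantiles of the
in-sample residuals — i.e. homoscedastic residual bands around the fitted
curve, not age-conditional quantiles. Heteroscedastic (GAMLSS-style)
centiles are deliberately out of scope. Classification is three-way with
inclusive boundaries: strictly below the lower bound → `decreased`,
strictly above the upper → `increased`, otherwise `normal`. Ages outside
the training span still yield a range but raise an `ExtrapolationWarning`.

By construction the band captures ~90% of null controls; the acceptance
run measures 0.900 on 2,000 held-out synthetic subjects.

## Personalized model (digital twin)

For a subject vector `Y` (length S):

1. **Neighbor selection.** The K = 30 controls minimizing the Euclidean
   distance to `Y` over all structures (Manhattan optional; ties broken by
   control row order). Euclidean is the plainest reading of "volume
   differences" between full normalized vectors.
2. **Manifold.** The K neighbors — not the subject — are embedded into
   d = 2 latent dimensions. The subject is projected out-of-sample through
   the fitted reducer's transform, so its residual is genuinely
   out-of-model. The default reducer is UMAP (seeded: `random_state` and
   `transform_seed` both derive from the config seed, making fits and
   transforms bit-reproducible); PCA is a pluggable deterministic
   alternative with exact linear-algebra semantics, used by the oracle
   tests and the large simulation studies. With identical neighbor rows
   the latent space collapses to the origin with a warning rather than
   failing.
3. **Kernel regression.** Nadaraya–Watson with an unnormalized Gaussian
   kernel (the constant cancels in the weight ratio). The bandwidth is
   picked from a grid — by default {0.1, 0.2, …, 2.0} × the median
   pairwise latent distance — minimizing the mean squared leave-one-out
   residual over the K training pairs; ties go to the smallest h. Weights
   always sum to 1, so twin predictions are convex combinations of the
   neighbors' volumes. If every weight underflows for a query, the nearest
   training point is returned with a warning; if every grid value leaves
   some training point weightless, fitting aborts with a `BandwidthError`.
4. **LOO calibration.** Each neighbor in turn is held out; manifold and
   regressor are refit on the remaining K − 1 (bandwidth re-selected
   within the fold), the held-out neighbor is projected and reconstructed,
   and its residual recorded. This yields K null residual vectors, their
   per-structure mean/sd, and empirical quantiles.
5. **Assessment.** Per structure: residual ε = Y − Ŷ; z-score
   (ε − mean_LOO)/sd_LOO (structures with sd_LOO = 0 are flagged
   `uncalibrated` and excluded from labeling); personalized range
   `[Ŷ + q_α(ε_LOO), Ŷ + q_{1−α}(ε_LOO)]` with α = 0.05 per tail,
   mirroring the baseline's 5%/95% thresholds; label via the same
   three-way classifier; and a permutation-style
   p = (1 + #{|z_held-out| ≥ |z|}) / (K + 1), our rank-based reading of a
   permutation test over the 30 nearest neighbors. No multiple-testing
   correction is applied across structures — the structures are modeled
   jointly, and per-structure raw labels are the intended output.

A subject that exactly matches a control row is excluded from its own
reference cohort with a warning. With fixed config and seed the whole
assessment is bit-reproducible for both reducers.

Design points that were genuinely open and how they were settled: the
manifold is fit on the 30 neighbors with the subject projected afterwards
(rather than embedding all 31 jointly), which keeps the subject strictly
out of the learned model; latent dimension defaults to 2; the abnormality
rule is the two-sided empirical-quantile band above rather than a
z-threshold, with z and p reported alongside for inspection.

## Evaluation statistics

The packaged 28-patient epilepsy fixture (surgery-confirmed focal cortical
dysplasia; columns: surgical location, radiological read, and the binary
outcome of each normative model) drives exact worked examples: detections
17/28 (personalized) vs 11/28 (average), subset counts 12 vs 8 among the
17 radiology-positive and 5 vs 3 among the 11 radiology-negative patients,
relative gain `round(100·(17−11)/11) = 55%`. Sensitivity is
detections/28 rounded half-up to two decimals: 0.61 and 0.39. Published
summaries of this cohort elsewhere give the personalized sensitivity as
0.67 while parenthetically stating 17/28 (= 0.607); 0.67 equals 17/28
rounded *up* only if mis-derived, and coincidentally equals the
radiological read's sensitivity — we treat it as a typographical
inconsistency and always compute from the counts.

McNemar uses the exact binomial form `p = min(1, 2·P(X ≤ min(b,c)))`,
`X ~ Bin(b+c, ½)` (p = 1 when b + c = 0): with b = 6, c = 0 discordant
pairs a chi-square approximation would be invalid. The Wilcoxon
signed-rank test drops zero differences, mid-ranks ties, and for n ≤ 25
computes the exact two-sided p by convolving the generating function
Π(1 + t^{2rᵢ})/2ⁿ of the signed-rank sum — exact even under ties, unlike
textbook tables; larger n uses the tie-corrected normal approximation.
The reported statistic is min(W⁺, W⁻) (configurable to W⁺).

## Synthetic cohorts

The generator emulates the tabular output of lifespan volumetry:

- ages uniform on 0.75–94 years; cohort 47% female; ICV log-normal with
  mean 1.45 × 10⁶ mm³ and log-sd 0.09;
- per-structure mean normalized volumes log-uniform on 0.05–2.5% of ICV
  (132 structures then occupy ~80% of the cavity, as in real
  segmentations), with mild mostly-declining quadratic age trajectories
  (linear and quadratic relative coefficients uniform on [−0.15, 0.02]
  and [−0.10, 0.02] over the centered, rescaled age);
- subject-level latent factors: a shared proportional scaling factor with
  between-subject sd 10% of each structure's mean (the dominant,
  age-independent "brain size / brain age" axis) plus two weaker random
  factors (sd 3%), giving the low-dimensional correlated structure the
  personalized model exploits;
- independent Gaussian measurement noise, sd 1.5% of each structure mean.

Structure-level parameters derive from `atlas_seed` (default: `seed`), so
independent cohorts can be drawn from one virtual population. Lesions are
multiplicative on a single structure's raw volume (factor 1.3 hypertrophy
/ 0.7 atrophy emulating focal cortical dysplasia); ICV and all other
structures are untouched, so the normalized value shifts by exactly the
factor.

What this simulator does **not** model: realistic anatomical covariance
atlases, site/scanner batch effects, non-Gaussian or nonlinear
subject-level variation, and segmentation failure modes. Passing tests
therefore demonstrate the statistical machinery under its stated
assumptions, not clinical performance on real MRI.

## Study sizes and numerical choices

The simulation studies in the test suite and acceptance script use 20
structures, 500 controls, K = 30, PCA reducer, α = 0.05: 500 null
subjects for the flag-rate calibration (nominal per-structure rate
2α = 0.10; measured 0.11), 200 factor-1.3 lesions for power (personalized
sensitivity 0.99–1.0 vs 0.74–0.79 for the age-based baseline at the same
nominal thresholds), and 2 × 2,000 subjects for lifespan coverage. These
sizes give stable estimates while keeping the default run fast; the full
132-structure default is exercised in the generator tests. Quantiles are
numpy linear-interpolation quantiles throughout. Polynomial fits use
`numpy.polynomial` least squares without rescaling (degrees ≤ 3 over ages
≤ 94 are well-conditioned).

## Known limitations

- UMAP's out-of-sample transform, while seeded and reproducible, is an
  approximation; PCA is preferred when exact geometry matters.
- The LOO null residuals are exchangeable with the test subject's residual
  only approximately: the subject is by construction at the center of its
  neighbor ball, while held-out controls may sit at its edge. Empirically
  the per-structure null flag rate stays within ~20% of nominal.
- Residuals are calibrated per structure independently; cross-structure
  residual covariance is not modeled.
- With K = 30 neighbors the empirical 5%/95% residual quantiles rest on
  30 points; α much below 0.05 is not meaningful at this K.
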
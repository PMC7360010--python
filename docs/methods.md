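# Methods

This note documents the models implemented in `petlimit`, the defaults of
the synthetic-data generator, the numerical conventions, and what the
package's tests do and do not demonstrate about real scanner data.

## The analysis chain

The scientific object is the detectability and quantification accuracy of
small deposits of ⁸⁹Zr-labeled cells on clinical PET systems, studied
in vitro with well plates.

**Quantification.** Each well is measured over a volume of interest (VOI):
a 3.4 cm diameter cylinder over the fill height for 6-well plates, a 1 cm³
cube for the cubic plate. Total well activity is the mean voxel
concentration (kBq/mL) times the VOI volume (mL). Detectability is the
contrast-to-noise ratio

    CNR = (μ_well − μ_background) / σ_background,

with μ_background and σ_background pooled over the voxel values of all
background VOIs of the plate (the empty wells on a 6-well plate; margin
regions between the well grid and the case on the cubic plate). The
sample SD (n−1) is used. Negative CNR values are retained by default
(`clip_cnr_at_zero` reproduces the floored convention); when the
background is exactly constant (σ = 0, only possible on noiseless
phantoms) the CNR is recorded as NaN rather than raising, so ideal-scanner
studies can still be quantified.

**Lower limit of detection.** Four steps: (1) ordinary least squares of
CNR on specific activity (SA) over all included wells; (2) a CNR
threshold — the upper bound of the 95 % confidence interval of the *mean
response* at SA = 0 (t distribution, n−2 df). Evaluating at zero label is
the most conservative choice and the evaluation point is configurable
(`lld_ci_at`), since "upper 95 % CI limit on CNR" admits several readings;
a prediction interval would be wider but the mean-response interval is
adopted. (3) The threshold is solved against the CNR-vs-cell-number
regression for the LLD in cells, and (4) against the CNR-vs-SA regression
for the LLD in specific activity. The Rose criterion (threshold = 5,
boundary inclusive) gives the companion rule. CNR is the response variable
in every regression. A threshold below a regression's intercept yields a
non-positive inversion; this is reported as-is (the limit is unconstrained
below the observed range), while a non-positive slope raises, since no
finite limit exists.

**Detection probability.** Wells are classified by the Rose criterion and
a binomial logistic model p(x) = 1/(1+e^{−(β₀+β₁x)}) is fitted by maximum
likelihood in cell number x. Complete separation makes the MLE diverge;
the fit then falls back to a fixed small ridge penalty (α = 10⁻⁴) and is
flagged (`ridge_fallback`), never silently. Single-class inputs are
inestimable and raise.

**Non-specific background simulation.** For each included well and each
fraction f ∈ {0.10, …, 0.80} the background is set to μ_b = f·μ_well with
Poisson-scaled noise σ_b = √(k·μ_b), and the CNR is recomputed as
μ_well(1−f)/√(k·f·μ_well) — strictly decreasing in f. Two conventions
matter:

- μ_well here is the *ambient-corrected* well concentration
  (VOI mean minus measured ambient background). The simulated non-specific
  background replaces the ambient one; feeding the raw VOI mean would give
  every well a CNR floor from the ambient term and make all wells
  detectable at small f.
- The calibration constant k (voxel-value variance per unit mean) is
  estimated from the measured plate backgrounds as σ²_b/μ_b when
  available, else 1. Under the package's own noise model
  k = 1/(noise_scale × voxel volume) exactly, so the estimate is
  self-consistent.

Per fraction, the logistic model is refitted and the 90 %-point reported.
A fraction where every well is detected still bounds the 90 %-point from
above by the smallest observed cell number (and from below by the largest
when none is detected); these bounds are flagged (`bound` column). The
expected behaviour — checked by the tests as a trend, not as strict
pairwise monotonicity, because per-fraction refits on ~31 wells show
sampling dips — is a rising 90 %-point with at least a ten-fold increase
from f = 0.1 to f = 0.8.

**Recovery model.** Per cubic well,
RC = (measured_well − measured_background)/known_well, with the known
background fixed at 0 kBq and the measured background taken as the mean
background concentration times the well-VOI volume. Across wells,

    RC_ij = a·ln(CD_ij·SA_ij) + γ₀ + u_i + ε_ij,

with shared slope a, population intercept γ₀ and a random intercept u_i
per scanner i. The natural logarithm is used: inverting the published-scale
coefficients (0.11, 0.57) at RC = 1, SA = 5.3 gives ≈ 9.4×10⁶ cells/mL,
a physically sensible density, whereas a base-10 reading gives ≈ 1.5×10⁹.
CD·SA is the activity concentration of the suspension in kBq/mL, so the
model says recovery rises logarithmically with how "hot" the suspension
is per unit volume. Fitting uses a linear mixed model (ML); with only two
scanner groups the variance component is weakly identified, so on
non-convergence the fit falls back to pooled OLS plus per-scanner
intercept deviations shrunk by their estimation variance
(`method = "shrunken_intercepts"`). Predictions are not clipped to [0, 1];
RC > 1 is a legitimate noisy measurement. `density_for_rc` is the exact
algebraic inverse of `predict_rc`.

**Decay and agreement.** Activity decays as 2^(−t/78.4 h); decay
correction divides by that factor and round-trips exactly. Pearson r
carries a two-sided t-test p-value; Bland–Altman reports mean difference
and bias ± 1.96·SD limits.

## The synthetic-data generator

`generate_study` reproduces the study design the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| experiments × plates | 6 × 2 | twelve 6-well plates, both scanner arms |
| wells per plate | 3 loaded | nominal 10⁶/10⁵/10⁴ cell levels |
| cell level medians | 1.08×10⁶, 1.45×10⁵, 8.5×10⁴ | log-normal jitter, σ = 0.45 (cosmetic) |
| specific activity | log-uniform 0.43–31.91 kBq/10⁶ cells | |
| QC exclusions | 5 of 36 wells | flagged, shared between arms |
| cubic plate | one 3×3, 1 cm³ wells | fixed loading spanning low/mid/high label |
| well counter CV | 3 % | multiplicative Gaussian, truncated at −1 |
| voxels | 1 mm isotropic | grid covers plate + 20 mm padding |

Scanner models (per arm): Gaussian PSF of 6 mm FWHM (PET/CT-like) and
5 mm (PET/MRI-like); ambient background 0.01 kBq/mL inside the plate
support (zero outside, like air on CT); a single Poisson stage at
2.5×10⁶ expected counts per kBq (≈ 25 counts per background voxel,
σ_b ≈ 2×10⁻³ kBq/mL). Blur is applied in continuous concentration space
before background and noise; the same plate truth is scanned by both
models with independent seeds, emulating sequential PET/CT then PET/MRI
sessions. All randomness derives from a single seed through spawned
`SeedSequence`s; identical seeds give byte-identical tables.

The noise floor is anchored to the study's printed observables rather
than to scanner physics (which the package does not model): it puts the
generated CNR ceiling near 10³, the Rose-rule limit at a few 10⁴ cells
and the CI-rule LLD one-to-two orders above it — the regime the reported
measurements describe. Resolution and noise of the real reconstructions
are unknown, so these remain config values, not claims about the GE
systems.

**Sedimentation.** In the cubic gel wells the activity occupies the bottom
`fill_fraction` of the well, with fill_fraction = clip(CD/1.0, 0.1, 1):
sparse suspensions settle into a thinner layer, deepening partial-volume
losses. This is the generator's mechanism for the observed coupling
between recovery and cell density — in a purely linear blur+noise model,
RC would be exactly independent of CD·SA (identical geometry, scaled
activity), so the intra-well distribution of cells is modelled explicitly.
The resulting empirical RC rises with CD but the fitted slope against
ln(CD·SA) (≈ 0.02 on default studies) is shallower than the published
0.11, because SA affects only counting noise here, not geometry; the
package therefore demonstrates the direction of the effect, not its
printed magnitude.

**What passing tests do not show.** The generator has no reconstruction
nonlinearity, scatter, randoms, attenuation, registration error or manual
VOI placement; its image-vs-counter correlations (r ≈ 0.999) are
accordingly tighter than real in-vitro data (r ≈ 0.84–0.85), and its
detection chain is cleaner than a clinical one. Tests passing on these
phantoms validate the *analysis* (formulas, inversions, estimators,
pipelines), not the scanners.

## Numerical conventions

- World coordinates are mm, voxel-center based, 0-based indices; a voxel
  belongs to a shape iff its center is inside. Cube and axial cylinder
  membership is half-open [lo, hi) so a 10 mm cube on a 1 mm grid holds
  exactly 1000 voxels (1 mL); circular membership is strict (x²+y² < r²),
  giving 889 voxels for a 34 mm disc slice.
- The rasterizer conserves activity exactly (sum × voxel volume = plate
  activity); Gaussian blur with ≥ 3×FWHM padding conserves it to < 0.1 %.
- Poisson counts are drawn once per voxel on the post-blur, post-background
  image; the reconstruction back to kBq/mL divides by the same counts/kBq
  factor, so the background obeys σ² = k·μ exactly.
- Stochastic operations require an explicit seed and raise otherwise.
- Problem sizes in the default test suite and acceptance run — one
  default study (24 plate scans at 1 mm voxels), 200-replicate parameter
  recoveries, 50-table oracle comparisons, 10⁴-draw counter calibration —
  were chosen to characterise the estimators well while keeping a full
  run in the low tens of seconds.

## Known limitations

- The two-scanner random-intercept model is at the edge of identifiability
  (2 groups); the shrunken-intercept fallback is deterministic and
  documented but not a full REML estimate.
- The ci95 LLD inherits the large sampling variance of a regression
  intercept estimated from ~31 heteroscedastic CNR values; across seeds
  the detection probability at the LLD is usually, but not always, above
  0.9 — the same fragility the two-regression procedure would show on
  repeated real experiments.
- `fill_fraction` is a one-parameter stand-in for intra-well cell
  distribution; it produces the qualitative RC–density coupling only.
- Cylindrical VOI heights are set from plate geometry plus one PSF FWHM
  (a deterministic stand-in for manual slice selection on coronal images);
  the axis is the plate normal by convention and configurable.
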
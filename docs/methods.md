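# Methods

## The diagnostic model

`tractdx` tests whether an individual's white-matter tracts show abnormally
low fractional anisotropy (FA) relative to a healthy reference cohort
scanned with the same protocol. The unit of analysis is the mean FA of a
large tract region of interest (ROI), computed over the voxels where the
tract's atlas label group intersects the white-matter skeleton. Working on
the skeleton limits partial-volume contamination; working with large tracts
avoids the unreliable tensor fits seen in small ROIs.

For each tract *j* the control cohort provides a mean `x̄_j` and sample
standard deviation `ρ_j` (n − 1 denominator). A subject with tract mean
`x_j` receives a deviation score

    z_j = (x_j − x̄_j) / ρ_j

converted to a two-tailed p-value from the standard normal distribution,
`p_j = 2·Φ(−|z_j|)`. The tract family (default: 10 ROIs) is corrected with
the Benjamini–Hochberg step-up procedure; the whole-brain skeleton mean
(`WSKL`) is a stand-alone summary tested uncorrected at the same α and is
never part of the family. A tract is *abnormal* only when it is
FDR-significant **and** `z_j < 0`: injury manifests as reduced FA, so
significant *increases* are reported separately (`high_fa`) and never
counted. The subject is classified *abnormal* when at least one tract is
abnormal; the whole-brain test is reported but excluded from this rule.

Assumptions: (i) the control tract means are approximately normal — this is
screened per tract with Shapiro–Wilk (α = 0.05) on the controls; (ii) all
volumes are co-registered to a common space (the package never registers or
resamples); (iii) patient and controls were acquired comparably, so the
control spread captures measurement plus biological variability.

### Non-normal tracts

When a tract fails the normality screen it is rank-inverse normalized:
controls and the tested subject are pooled, ranked (average ranks for
ties), and mapped through Blom scores `Φ⁻¹((r − 3/8)/(n + 1/4))`. The
reference mean/SD and the subject's z are then computed on the transformed
values. Pooling the subject bounds how extreme their transformed value can
be (the most extreme rank maps to a finite quantile); results therefore
carry an `extreme_rank` flag whenever the subject sits outside the control
range, signalling that the reported |z| is rank-limited.

### Age correction

FA declines with age, approximately quadratically over adulthood. The
optional age model fits, per tract, ordinary least squares of mean FA on
`[1, age, age²]` and replaces values by residuals; the tested subject is
residualized with the same coefficients. The default fit cohort is
controls-only, which keeps patient pathology out of the age coefficients; a
pooled option (patients + controls) is available and reproduces the
conventional normative-residual workflow. With no true age trend the
correction leaves classifications essentially unchanged; with a trend and
an age-offset subject it removes a bias of `β₁·Δage/ρ` z-units.

### Lesion handling

Focal lesions (contusions, missing brain) would drag a tract's mean FA down
for reasons unrelated to diffuse axonal injury. A binarized lesion mask
(rebinarization threshold after any resampling: 0.5, configurable) is
subtracted from **every** tract mask and from the whole-brain skeleton, and
the same corrected masks are used for the patient *and* every control, so
the reference is rebuilt per lesioned patient (`mask_version` tracks this).
A tract emptied by the subtraction is flagged missing, excluded from the
FDR family (the family size m shrinks), and reported. In longitudinal use
the lesion mask delineated at the first (subacute) timepoint is applied at
both timepoints so within-subject comparisons sample identical voxels.

## Tract panel selection

Candidates (an ICBM-DTI-81-style catalog, typically 46 ROIs) pass three
filters: (1) voxel count at least the catalog median (strictly smaller
tracts are excluded; ties at the median survive); (2) test-retest ICC
strictly above 0.6 — the conventional "good reliability" cut — estimated
from repeat scans of healthy controls (single-measure, two-way
random-effects absolute-agreement ICC(2,1) by default; consistency ICC(3,1)
by flag); (3) intersection with a curated panel encoding anatomical
coverage of association/projection/commissural pathways and clinical
relevance, which are irreducibly human judgements and are therefore config,
not code. The shipped default panel is the 10-ROI set CCB, CCG, CCS,
CST_L/R, CR_L/R, ILF_L/R, MCP. An ICC of exactly 0.6 is excluded ("above"
is strict); a curated tract that fails an earlier filter is warned about,
never resurrected. Whether repeat scans over three years are summarized by
one k=3 ICC or averaged pairwise ICCs is a free choice; the package uses
the single k-timepoint ICC.

## Evaluation experiments

**Leave-one-out specificity.** Each control is diagnosed against the
remaining n − 1. The fraction classified abnormal estimates the
subject-level false-positive rate; under the pipeline's own α = 0.05 and
the BH family this sits near 2–3% for 10 correlated tracts (only the low
tail counts, and correlated tests reject together), comfortably below the
5% acceptability bound.

**Control-sample-size experiment.** For sizes 10–50, subsamples are drawn
without replacement, the reference re-estimated, and every patient
rediagnosed; 100 iterations per size. A tract is *consensus-abnormal* when
flagged in strictly more than 5% of iterations (>5 of 100). Consensus
subject classifications are scored against the full-cohort classification:
TP/FP/TN/FN at the subject level, with sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV and NPV. These are reliability measures
relative to the full cohort, not accuracy against pathology. Reliability
within a size is additionally summarized by the ICC of FDR-corrected
p-values across iterations (patients as subjects, iterations as raters;
consistency model, since iteration identity is arbitrary). The seed
hierarchy is master → per-size → per-iteration, making reports
bit-reproducible.

**Longitudinal reliability.** Two patient timepoints are diagnosed against
the same controls; per-tract ICCs of z and of FDR p-values across patients
quantify agreement (consistency model by default, so a uniform
progression-related shift does not destroy "reliability"), together with a
2×2 classification-agreement table.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, not
brain geometry:

- per-tract control mean FA ~ multivariate normal; defaults: 10 tracts,
  means spread 0.45–0.75, SDs 0.015–0.03, equicorrelation 0.5 (tract FA is
  empirically correlated; this also exercises BH under dependence);
- ages uniform 20–70 y with a linear decline of −5·10⁻⁴ FA/year (quadratic
  term available), anchored at the reference age 45;
- injured patients are control draws minus `effect_size` control-SDs
  (default 4) in `n_injured_rois` random tracts (default 4);
- whole-brain mean = equal-weight tract mean plus N(0, 0.005) residual, so
  the stand-alone test is correlated with, but not redundant to, the tracts;
- longitudinal second timepoints add independent measurement noise (0.3 SD
  units, giving a test-retest ICC near 0.9 as seen in repeat-scan FA data)
  and an extra decline (default 0.5 SD) in injured tracts; the whole-brain
  residual is treated as a stable per-subject offset across timepoints;
- voxel-level datasets place each tract in a disjoint box on a 32³ grid
  with a one-voxel-thick skeleton plane, voxel noise SD 0.05, and spherical
  lesions — sufficient to test masking, extraction and lesion locality
  exactly, while representing nothing about real anatomy, registration
  error, or skeleton-projection artefacts.

Draws are pure functions of (config, seed); FA values are clipped into
(0, 1) with a warning (defaults never trigger clipping). Because the
generator is idealized — Gaussian tracts, exchangeable controls, exact
co-registration — passing tests demonstrate the statistical machinery is
correct and calibrated under its stated assumptions; they do not
demonstrate robustness to scanner drift, registration failure, or
non-Gaussian pathology.

## Numerical choices

- Sample SD uses the n − 1 denominator; control variance numerically at
  zero (SD ≤ 1e-12) is an error, since z is undefined.
- Two-tailed p from the normal CDF; a Student-t option with n − 1 df exists
  but differs negligibly at n ≈ 100.
- FDR: Benjamini–Hochberg by default; Benjamini–Yekutieli by flag for
  strongly dependent families.
- Skeleton derivation from a mean-FA volume keeps voxels with FA ≥ 0.2.
- Grid equality requires affines equal within 1e-4; mismatches always
  raise, nothing is ever silently resampled.
- Zero-valued voxels inside ROI ∩ skeleton are legitimate skeleton voxels
  and are included in means; a mean over an empty voxel set is never taken.
- Ties in the rank-inverse transform share average ranks; the Blom offset
  (3/8) is used throughout.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run at the study's native scale
where that is cheap — 103 controls, 10 tracts, 100 subsample iterations per
size, 200 leave-one-out null cohorts — and at reduced scale (fewer seeds or
patients) for ancillary property checks. The voxel-level end-to-end checks
use 32³ grids with 12–20 subjects.

## Known limitations

- Upstream processing (tensor fitting, TBSS registration and skeleton
  projection, lesion delineation) is out of scope: inputs must arrive
  skeletonized and co-registered.
- The deviation score is univariate per tract; no multivariate
  (e.g. Mahalanobis) or Bayesian normative model is provided.
- Detection power is bounded by the subject's own sampling noise: a true
  −4 SD deviation in one tract is detected in roughly 88–92% of subjects
  at n = 103 controls with a 10-tract BH family, not always; certainty
  requires deeper deficits (≈ −5 SD and beyond).
- The subsample experiment's "sensitivity/specificity" are agreement rates
  with the full-cohort diagnosis, which is itself an estimate.
- Cross-scanner harmonization is not addressed; the control cohort must
  match the patient's scanner and sequence.
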
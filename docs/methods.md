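# Methods

## Segmentation model

A PET scan is a 3D grid of SUV values (dimensionless, non-negative); the
world coordinate of a voxel center is `origin + index · spacing` (0-based
indices, spacing in mm), and one voxel is `prod(spacing)/1000` mL. The
segmentation threshold follows the PERCIST/PROMISE convention: statistics of
a reference region of healthy tissue define the cut-off for "PSMA-positive".

* liver reference: 30 mm diameter sphere, `threshold = 1.5·mean + 2·SD`;
* aorta reference (for patients with known liver metastases): 10 mm diameter
  cylinder extending 20 mm along z, `threshold = 2·mean + 2·SD`.

The ROI is the set of voxels whose centers fall inside the geometry; it must
lie inside the grid and contain at least 10 voxels, otherwise the statistics
are refused as unstable. The **mode is an explicit flag** — the pipeline
never tries to auto-detect liver metastases.

Lesions are maximal connected components of voxels with `SUV > threshold`
(strict inequality — the choice at the boundary is measure-zero on
continuous data but fixed for reproducibility), after removing an exclusion
mask. On real data the exclusion mask is the programmatic stand-in for the
manual reader correction of physiologic uptake; in this package it always
contains the reference ROIs themselves. Numerical conventions, each
configurable:

* voxel connectivity 26 (default; 6 and 18 available). 26 is the most
  permissive choice and merges diagonally-touching lesion voxels the way a
  human reader would read them as one lesion;
* SD of the reference ROI: sample SD (ddof = 1);
* minimum component size 1 voxel (no minimum); raise it to suppress noise
  speckles.

Per lesion: SUVmax (max voxel value) and volume (voxel count × voxel
volume). Lesions are ordered by descending SUVmax with centroid-lexicographic
tie-breaking; that order defines `lesion_id` and makes every downstream
tie-break deterministic.

## Keyhole reduction and response model

For a summed quantity X (summed SUVmax or summed tumor volume over a lesion
subset), the therapy-induced change is

    rel. ΔX(%) = X_followup / X_baseline × 100 − 100,

undefined (an explicit error, never a silent NaN) when the baseline sum is
zero. Subsets: all lesions, the 10 and 5 hottest (SUVmax family, plus the
single hottest lesion as top-1) and the 10 and 5 largest (volume family).
**Top-k subsets are re-ranked independently at each timepoint**; there is no
anatomical matching of lesions between scans, so a new lesion at follow-up
competes for the top-k on equal footing. This is the largest semantic choice
in the package: the summed metrics are per-scan rankings, and whether one
should instead track baseline lesions into the follow-up scan is a different
(registration-based) procedure that is out of scope. If a patient has fewer
than k lesions all lesions are used, which collapses the all/10/5 variants
onto each other — such patients are flagged (`fewer_than_5_lesions`).

Classification at ±30 % relative change: PD for Δ ≥ +30, PR for Δ ≤ −30, SD
strictly between. Both boundary conventions are deliberate: at exactly +30
progression wins (clinically the safer call), at exactly −30 the change
counts as response. Classification uses the full-precision Δ; rounding is a
display concern only. Discrepancy grading between the whole-body call and a
reduced call is symmetric in the labels: *relevant* iff exactly one of the
two is PD, *non-relevant* for PR vs SD, *concordant* otherwise.

## Correlation analysis

Spearman's rank correlation of ΔPSA with each imaging Δ, per cohort label.
r is the Pearson correlation of mid-ranks (average ranks on ties). The
p-value is two-sided: for n ≤ 10 an exact permutation probability
P(|r_perm| ≥ |r_obs|) over all n! permutations of one margin (computed
vectorized; a ulp-scale tolerance guards the ≥ comparison against float
noise), for n > 10 the Student-t approximation `t = r·√((n−2)/(1−r²))` with
n − 2 df. The crossover is covered by a test showing the two methods agree
to a few percent at n = 10/11. Significance is flagged at p < 0.05; no
multiple-testing correction is applied across the table cells. Cohorts with
fewer than 3 patients, or constant inputs, yield missing cells rather than
errors. No ties correction beyond mid-ranks is applied to the exact
enumeration; with continuous synthetic inputs ties have probability zero.

## Synthetic data model

The generator emulates exactly the features the pipeline consumes, not PET
physics.

**Phantom.** Default grid 40³ voxels at 4 mm isotropic spacing (a 160 mm
field of view — a scaled-down torso chosen to keep desk-scale cohort runs
fast); background SUV ~ N(1.0, 0.25) clipped at 0 (SUV is non-negative; with
these defaults the clipped mass is ~3·10⁻⁵ so the clipping does not
meaningfully distort the distribution); liver sphere (organ radius 18 mm,
SUV ~ N(5.0, 0.5)) and descending-aorta cylinder (radius 7 mm, length 60 mm,
SUV ~ N(1.8, 0.3)). The default liver threshold is therefore
1.5·5.0 + 2·0.5 = 8.5 SUV, sitting between background and lesion peaks —
these are configuration values, not constants. Lesions are spheres with a
truncated-paraboloid intensity taper,

    SUV(r) = bg + (peak − bg)·(1 − (r/R)²),  r ≤ R,

painted by voxelwise maximum over the background draw. The taper makes
SUVmax well defined (the configured peak, up to the half-voxel offset of the
nearest voxel center) and makes the recovered volume an analytic function of
the threshold: the suprathreshold fraction of the sphere volume is
`(1 − (T − bg)/(peak − bg))^{3/2}`. Geometry is seed-independent; the seed
only drives noise, and identical configurations reproduce volumes bit for
bit. Lesion spheres must not intersect the reference ROIs (validated on
every phantom, with placement headroom for follow-up growth); overlap with
the liver *organ* outside its ROI is allowed — liver metastases exist.

Measured against the analytic sphere volume (4/3·π·R³), a 10 mm lesion at
2 mm spacing and a threshold just above background recovers the volume
within 15 % (a grid-refinement sweep at 4/2/1 mm shows the discretization
error shrinking monotonically, toward the taper-aware analytic value).

**Response.** A scenario scales each lesion's volume by a factor ≥ 0 (radius
by its cube root; 0 = vanished), scales peaks by an intensity factor, and
adds new follow-up lesions. Ground truth uses analytic sphere volumes and
the same relative-change code path as the pipeline. The cohort generator
draws 1–15 lesions per patient (uniform; so sub-5-lesion patients occur
regularly), radii 4–10 mm, peaks 15–40 SUV; a log-normal per-patient
response factor exp(N(−0.3, 0.6)) (median −26 % volume change, a realistic
mix of responders and progressors), mild per-lesion log-normal jitter
(SD 0.15) and near-unity intensity jitter (SD 0.05; PSMA uptake intensity is
treated as far more stable than volume, which also keeps the thresholded
volume fraction comparable between timepoints), volume scales capped at
3.375 (radius growth ≤ 1.5×, the placement headroom), vanishing below scale
0.05, and Poisson(1) new lesions for patients progressing beyond factor 1.1.
PSA baselines are log-normal (median 60 ng/mL).

**PSA coupling.** Only rank structure is asserted downstream, so ΔPSA is
coupled to the true ΔTV through a Gaussian copula: with target Spearman ρ_s,
the latent Pearson coefficient is ρ_p = 2·sin(π·ρ_s/6) (the bivariate-normal
relation); the normal scores of ΔTV are mixed with independent N(0, 1) noise
at ρ_p, and ΔPSA = 100·(exp(0.9·z − 0.25) − 1), a fixed monotone transform
bounded below by −100 %. At ρ_s = 1 the noise coefficient is exactly 0 and
ranks coincide exactly. A 200-replicate Monte-Carlo check at n = 65 shows the
mean sample Spearman within ±0.05 of the target, both at truth level and
after running every scan through segmentation (the pipeline's measured ΔTV
rank-correlates with the true ΔTV at ≈ 0.98 under these defaults).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomy (no organs beyond the two reference
regions, no bladder/kidney physiologic uptake), scanner physics (no PSF,
attenuation, reconstruction artifacts or SUV calibration error), non-sphere
lesion shapes, lesion coalescence/fragmentation between scans, and reader
variability. Results on synthetic cohorts validate the *procedure*, not the
clinical performance of any threshold on patient scans.

## Constructed study scenarios

Two cohorts are constructed (not sampled) to demonstrate the two ends of the
keyhole approach's behavior:

* **uniform-response cohort** (16 patients, ≤ 12 lesions each): every lesion
  of a patient scales by one common factor drawn from a grid that avoids the
  bands around the ±30 % boundaries (volume factors near 0.7 and 1.3), no
  new or vanished lesions. Whole-body and top-k changes then coincide up to
  voxelization noise, so every patient is concordant — zero relevant
  deviations by construction.
* **adversarial new-lesion patient**: five large lesions (8–9 mm) unchanged
  at follow-up plus twelve new small lesions (5–6 mm, all with one common
  peak SUV so the threshold cuts the same volume fraction from every
  lesion). Whole-body tumor volume rises well past +30 % (PD) while the five
  largest follow-up lesions are exactly the unchanged baseline ones (SD):
  a clinically relevant deviation that the top-5 reduction cannot see.

## Problem sizes and numerical choices

Cohort validation runs use 65-patient cohorts on the 40³/4 mm default grid,
200 replicates — sizes chosen so a full validation pass completes in
minutes on one CPU while keeping the per-cohort sampling error of Spearman's
r (SD ≈ 0.065 at n = 65, ρ ≈ 0.6) well characterized; the single-cohort
acceptance envelope (0.30, 0.90) is that mean ± ≈4.6 SD. Floating-point
tie-breaks are removed by the deterministic lesion ordering; comparisons
that can be hit by summation-order noise use small absolute tolerances
(1e-12 relative in tests). Degenerate inputs fail loudly: zero-lesion
baselines (undefined relative change), constant correlation inputs, ROIs
outside the grid, overlapping lesion/reference geometry, negative SUV.

## Known limitations

* No lesion tracking between timepoints (by design; see above).
* The generator's response distribution is a modeling choice exposed as
  configuration — real treatment-effect distributions per therapy line are
  not modeled.
* The exact-p enumeration is O(n!) and is limited to n ≤ 10; above that the
  t-approximation is used (adequate at cohort sizes here, as the crossover
  test shows).
* Phantoms are text-free synthetic constructs; no DICOM ingestion, SUL/SUV
  variants, or organ-level (miTNM-style) sub-classification.
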
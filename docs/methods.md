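# Methods

This note documents the models implemented in `nfq`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was open.

## Measurement chain

**Registration.** MRI-to-PET/CT co-registration uses six paired skull
fiducials (eyes, mandibular condyles, cochleae) and the closed-form
least-RMS rigid fit: centroids are aligned and the rotation is the SVD
solution of the cross-covariance (Kabsch), with the smallest singular
vector flipped when the raw solution is a reflection. This is the unique
minimizer of the RMS paired-point distance over proper rotations, so no
iterative optimization is needed. Atlas normalization is a 12-parameter
least-squares affine on the same landmarks — a deliberate, documented
simplification: the original processing normalized each animal's CT to an
atlas CT with an intensity-based tool, but on schematic phantoms a
landmark affine is deterministic, exact for affine scenes, and exercises
the same resampling path. CT itself is not simulated; the atlas frame
plays the CT-proxy role. Volumes are resampled with trilinear
interpolation (images) or nearest-neighbour (labels; label set provably
preserved), out-of-field voxels set to background. World coordinates are
RAS mm with NIfTI voxel-to-world affines; voxel indices are 0-based.

**PET quantification.** SUV = activity / (dose/weight); dose and weight
must be positive, decay and scatter corrections are assumed already
applied in the input activity images. The 20–50 min analysis window is
collapsed by a *duration-weighted mean* rather than a plain sum: for the
standard six equal 5-min frames the two differ by a constant factor that
cancels in SUVR, and the weighted mean stays correct for unequal frames.
VOI values are arithmetic means over atlas label voxels, computed after
label propagation to a common grid; an empty VOI is an error, never a
silent NaN. SUVR divides by the neocortex mean; when a cortical
lesion-exclusion mask is supplied the reference mean is recomputed over
the unaffected neocortex voxels only. The mask is an explicit input: the
underlying protocol gives no operational criterion for "evidence of
cortical lesions", so automatic lesion detection on PET is deliberately
out of scope.

**SPIO quantification.** Brain extraction: Otsu threshold, largest
connected component, morphological closing (radius-1 ball), hole filling.
The morphology runs on an edge-replicated pad so that a head clipped by
the field of view does not leak holes through the array border. Bias
correction fits log-intensity over the brain mask with a full 3D
polynomial basis of order 2 (10 terms) by least squares, then does one
reweighting pass that zeroes the weight of residuals below −2 robust SDs
so hypointense lesions do not drag the fit; the field (exponential of the
fitted polynomial) is normalized to mean 1 over the mask and divided out.
Idempotence to <0.5% RMS is tested. SPIO labelling models the within-mask
histogram with a single dominant tissue mode located robustly (median,
1.4826·MAD); voxels below μ − kσ with k = 3 (exposed parameter) are
labelled and clusters smaller than 2 voxels are discarded as noise. The
threshold derives from the data's own histogram, making labelling
invariant to global intensity rescaling. The exact thresholding rule of
the original MATLAB tool is unpublished; this robust-mode/k·σ rule is the
simplest model consistent with labelling hypointense sites, and k is
exposed. SPIO-Vol denominators are full atlas VOIs (not brain-masked
VOIs), a documented choice where the original is silent.

**Statistics.** Two-sided tests at α = 0.05 throughout. Mann-Whitney U
uses the exact null distribution (full rank-partition enumeration,
delegated to scipy and verified in the tests against an independent
itertools enumeration oracle) when n₁+n₂ ≤ 14 with no ties, else the
normal approximation with tie and continuity corrections; the method used
is recorded on every result. Spearman correlations are tie-aware
(average ranks) with the t-approximation p-value, and constant inputs
return a flagged undefined result rather than 0. Correlations pool EAE and
CTR animals, matching the original analysis; note the caveat that pooling
two separated groups inflates rho relative to within-group association.
Region-wise p-values are reported uncorrected (again matching the
original reporting); a Holm adjustment is available but off by default.

## Synthetic phantom model

The phantom is schematic by design: nested ellipsoids sized as fixed
fractions of the grid field of view, so the scene scales with the grid. At
the reference 64³ / 0.2 mm grid the regions have mouse-like volumes
(hippocampus ≈ 19 mm³, thalamus ≈ 18, caudate/putamen ≈ 17, cerebellum
≈ 54, brainstem ≈ 31, neocortex shell ≈ 150 mm³). The pipeline default is
64³ / 0.3 mm: with the fixed 0.9 mm PET PSF this puts the thinnest VOI
several PSF widths across, representing the favourable case in which VOI
definition is not partial-volume-limited; at strict mouse scale the
cerebellum/brainstem partial-volume bias alone approaches the 10%
recovery band. Six fiducials sit outside the brain at skull-plausible
positions with ±0.15 mm per-build jitter.

**PET.** Regional activity is `reference_suv · dose/weight` scaled by the
per-region uptake ratio (neocortex ≡ 1, reference_suv default 0.21 —
the scale of cortical TSPO-tracer uptake), extracerebral soft tissue at
0.6× reference, blurred by an isotropic Gaussian PSF (default FWHM
0.9 mm), with additive Gaussian noise per frame (default SD 5% of
reference activity). Noise is Gaussian on activity, not Poisson on
counts: post-reconstruction images are approximately Gaussian, and the
simple model is exactly seedable. Six 5-min frames starting 20 min
post-injection.

**SPIO-MRI.** The volume is rendered directly on its own native grid:
the atlas labels are nearest-resampled through the rigid misalignment
(default ≤5°, ≤1.5 mm) into the native frame and lesions are painted
there, so lesion edges are crisp and the realized per-region fraction is
recorded *exactly* from the native mask — requests that cannot be met with
punctate clusters fall back to the nearest achievable value, always
recorded. Lesions are non-overlapping spheres of radius 1–3 voxels,
rejection-sampled wholly inside their region and at least one voxel below
the pial surface (intraparenchymal, as perivascular uptake sites are; this
also guarantees they are enclosed holes for brain extraction). Tissue is
N(100, 5), lesions sit at 100·(1−contrast) with contrast 0.7; the bias
field is the exponential of a random second-order polynomial scaled to
the requested peak deviation (default 20%) and normalized to mean 1 over
the brain. No MR physics (TE/TR/T2*, k-space) is modelled.

**Cohort model.** Group-level regional measurements follow the published
group summaries of the PLP-EAE acute phase (per-region EAE and CTR
mean ± SD for both SUVR and SPIO-Vol; e.g. cerebellum SUVR 2.4 ± 0.2 vs
1.9 ± 0.3, SPIO-Vol 14.5 ± 7.5 vs 3.9 ± 2.8). Each animal carries a
latent severity factor z ~ N(0,1); each (region, metric) value is drawn
through a Gaussian copula with loading 0.8 on z. Marginals are
moment-matched: SUVR normal, SPIO-Vol gamma — fractional volumes are
nonnegative and the reported SDs are on the order of the means, implying
right skew. This one construction yields (i) exchangeable groups under a
null profile (EAE moments set to CTR moments), (ii) group separations on
the reported scale, and (iii) within-animal cross-region coupling that
drives the clinical-score link. The clinical score is a monotone function
of total lesion burden (default: linear map onto the 0–4 scale rounded to
half points; strictly monotone continuous links are supported for
validation studies); controls are healthy with CS 0. Doses (5.55–7.0 MBq)
and group-specific body weights match the study's reported ranges.

**Fluorescence.** Round Gaussian cell blobs on a noisy background;
channel B is a pan myeloid marker present on every cell, a fraction
`frac_double` of cells co-express channel A, so the expected pixel
co-localization |A⁺∩B⁺|/|B⁺| equals `frac_double`. The cell table records
centroids, memberships and distances from a vessel-disc border. The
co-localization denominator is the marker-positive (Iba1) pixel count —
the quantity is "extent of TSPO expression within marker-positive cells" —
with the alternative denominators exposed.

**What the phantom does not emulate.** Anatomy (shapes are ellipsoids),
PET count statistics and reconstruction artefacts, MR physics and
susceptibility blooming, spatially correlated noise, imperfect atlas-VOI
correspondence, and the PET/MRI session-day gap (both modalities are
rendered from the same disease state; the in vivo clinical score changed
between sessions). Passing recovery tests therefore demonstrates the
correctness and calibration of the *measurement chain*, not robustness to
real-data nuisance factors.

## Validation studies and problem sizes

The validation layer (`nfq.validation`) runs each study at a size chosen
to keep the full suite fast while holding Monte-Carlo noise well below
the asserted bands: 100 rigid refits (0.05 mm landmark jitter; the
reported RMS is pooled over the study and the rotation error is the mean
— worst-case order statistics of unbounded Gaussian jitter are not a
meaningful bound); one 64³ bias/SPIO/SUVR phantom each; 100
enumeration-checked Mann-Whitney draws covering all pooled sizes ≤ 14;
1200 null cohorts for type-I calibration (one rotating region/metric cell
per cohort, so pooled rejections are i.i.d. binomial — cells within one
cohort are correlated through the severity copula); 1500 cohorts for
power and 300 for pooled correlations.

Two power cells deserve an honest caveat. Under the reported group
moments at n = 7 vs 5, the exact Mann-Whitney test has true power ≈ 0.74
for thalamus SPIO-Vol (7.3 ± 5.5 vs 1.6 ± 1.7) — below the 0.8 bound the
acceptance test asserts, and consistent with that contrast reaching only
marginal significance in vivo — and ≈ 0.80 for cerebellum SUVR, i.e.
exactly at the bound, so a seeded estimate can fall on either side. These
assertions are kept as stated rather than weakened; the corresponding
test can legitimately fail on those cells.

## Known limitations

- Atlas normalization is landmark-affine; nonlinear warps are out of
  scope, so anatomically realistic inter-subject variability is not
  handled.
- The SPIO threshold rule (robust mode, k = 3, min cluster 2) is a
  documented stand-in for an unpublished rule; k and the cluster size are
  exposed parameters.
- SUVR recovery under PSF blur carries a partial-volume bias that grows
  as VOI thickness approaches the PSF width; no partial-volume correction
  is applied (out of scope).
- T2-weighted RARE images are accepted but unused in quantification
  (hypointensity labelling operates on the T2*-weighted GRE volume).
- Kinetic modelling, arterial input functions, R2*/QSM iron
  quantification, and spinal-cord imaging are out of scope.
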
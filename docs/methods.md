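# Methods

This note documents the models, conventions and numerical choices behind
`lipoglo`, and what the synthetic-data generators do and do not emulate.

## Gel densitometry and ladder-unit registration

A lane is the row-wise sum of image intensity over the lane's columns,
taken from the loading-well row (the origin, 0 LU) downward; migration
increases with row index and coordinates are 0-based. The DiI-LDL
standard band defines the ladder unit: its migration distance in pixels is
1 LU, which makes lanes comparable across gels regardless of run time,
voltage or gel batch. The standard is a registration fiducial only — the
fact that human DiI-LDL migrates somewhat more slowly than zebrafish LDL
does not enter the arithmetic.

**Peak detection.** The standard's band is located as the peak of the
moving-average-smoothed profile (default window 5 rows, boundary-replicated).
Smoothing flattens a narrow band into a plateau, so the peak is taken as
the center of the first maximal plateau; this breaks exact ties toward the
smaller migration distance while preserving the true peak row of a
symmetric band. A flat profile (max = min) is rejected as "no standard
detected".

**Binning.** Default class boundaries are 0.3 / 1.0 / 1.7 / 2.4 LU for
ZM / VLDL / IDL / LDL. Bins are half-open `[lower, upper)`; signal at
exactly 0 LU belongs to ZM and signal beyond the nominal 2.4 LU edge is
assigned to LDL, so every pixel is classified and lane totals always reach
100% (abundance is strictly relative — the assay says nothing about
absolute particle counts). No background subtraction is applied by
default: in-gel chemiluminescent background is negligible relative to
signal, and relative quantification is insensitive to a small uniform
offset.

## Density-gradient calibration

Fraction density (g/mL) comes from the refractometer reading via the
linear iodixanol calibration *D* = 3.3508·RI − 3.4675; readings at or
below RI = 1 are physically impossible for aqueous media and rejected.
Fraction 1 elutes from the dense tube bottom first, so densities should
decrease with fraction index; any local increase is *flagged* as an
inversion (a disturbed gradient) rather than treated as an error.
Fraction 1 is conventionally excluded from electrophoresis-linked analyses
(its protein and iodixanol load distorts native gels), which is why the
shipped gel layout dedicates lane 1 to the DiI standard.

Mobility calibrations are ordinary least-squares degree-2 polynomials with
R² = 1 − SS_res/SS_tot. Two published reference curves ship as constants:
mobility → density (0.0796, −0.1886, 1.136; R² = 0.97737) and
mobility → diameter (10.82, −44.551, 70.125; R² = 0.79978). The second
curve was originally captioned as a mobility–density relation, but its
values are on the nanometre scale (≈ 36 at 1 LU) and sit in the context of
the EM diameter measurements; rather than hard-coding a guess, every
`CalibrationCurve` carries explicit `x_role`/`y_role` labels and the
shipped constant is labelled `diameter_nm`. Numerical conventions: a fit
needs ≥ 3 distinct x values; a zero-variance response is treated as a
perfect constant fit (R² = 1), avoiding 0/0. Diameter summaries use the
arithmetic mean and the n−1 sample SD, with SD defined as 0 for n = 1.

## Whole-larva imaging

Each larva yields a 10 s and a 30 s chemiluminescent exposure; the frames
are proportional (ratio 3.0) until the long frame clips at the camera bit
ceiling. Quantification uses the 30 s frame unless it contains saturated
pixels *within the union of the region masks* — a hot pixel off the larva
should not force the noisier short exposure (the restriction to in-mask
pixels is this package's choice; the assay description does not specify).
If both frames are saturated in-mask the stack is rejected ("dynamic range
exceeded"). Region masks (viscera / trunk / head) are user-supplied label
images; automatic segmentation is out of scope because the anatomical
boundaries are not defined quantitatively. Output fractions are each
region's intensity sum over the three-region total, which makes them
invariant to any positive rescaling of the image; background (label 0) is
ignored and blank subtraction is again unnecessary.

## Plate-based counting

Wells are summarized per (group, timepoint) with mean, n−1 SD and a low-n
flag. The allele-dosage check reports the ratio of group means with a
percentile-bootstrap interval (default B = 1000, seedable); the ratio is
scale-invariant. Pigment attenuation of luminescence is a known covariate
of the real assay that is deliberately not modelled — a free-text
covariate column passes through for users who correct externally.

## The statistical decision tree

1. **Levene's gate** (center = mean, the classical form — the procedure
   names Levene without a variant, so the median-centered Brown–Forsythe
   flavour is not used). p < 0.05 routes to the heteroscedastic branch.
2. **Uniform variance:** one-way ANOVA, Tukey HSD post hoc.
3. **Unequal variance:** Welch's ANOVA (inverse-variance weights,
   Welch–Satterthwaite denominator df) with Games–Howell post hoc
   (pairwise q with per-pair Satterthwaite df, p from the studentized
   range at the full group count k).
4. **Two factors** (e.g. genotype × stage): robust two-way ANOVA — all
   pairwise linear contrasts of 20%-trimmed cell means per effect, with a
   percentile-bootstrap null (default B = 599): cells are resampled with
   replacement, and the p-value measures how deeply the zero-contrast
   point is nested in the bootstrap contrast cloud (Mahalanobis distance
   under the bootstrap covariance, with a tiny ridge against degenerate
   clouds). Each cell needs n ≥ 4 and the layout must be complete.
   Games–Howell follow-ups run per factor level on untrimmed data.
5. **Multiplicity:** Bonferroni across the per-subclass (k = 4 →
   0.0125) or per-region (k = 3 → reported 0.017) families; reported
   thresholds are rounded half-up to 3 decimals.
6. **Calls:** per class/region and timepoint, treatment vs control by
   Games–Howell at p < 0.05, direction from the sign of the mean
   difference — the up/down arrowheads on the stacked-area plots.

Levene, the classical F and Tukey HSD delegate to scipy (the
studentized-range CDF is scipy's quadrature implementation, checked in the
tests against the published critical value q(0.05; k=3, df=10) = 3.88);
Welch's ANOVA, Games–Howell and the robust two-way test are implemented
here. Identity oracles: at k = 2, Tukey reduces exactly to the
pooled-variance t test and Welch's ANOVA to the Welch t test (F = t²);
Games–Howell approaches the Welch t p-value. The "Welch equals classical
F under equal variances" limit is exact at k = 2 for balanced groups with
equal sample variances and holds asymptotically otherwise, which is how
the test suite encodes it.

## What the synthetic generators emulate

All generators are pure functions of (parameters, seed) with byte-stable
output, and every artifact carries a ground-truth sidecar.

* **Gel lanes:** mixtures of Gaussian bands in LU space. The real assay's
  band shapes are smooth and unimodal but have no published functional
  form; Gaussians are the minimal choice. Preset band widths (σ =
  0.05–0.10 LU) keep > 99% of each band's mass inside its bin so the
  closed loop can be audited at the 1%-absolute level. Genotype presets
  are *qualitative* encodings of the published profile shapes (e.g. the
  apoC2 mutant VLDL weight 0.7, the mtp mutant's bimodal LDL doublet at
  1.90/2.20 LU); they are declared fixtures, not estimates of real data.
* **Gel images:** two 16-bit channels (NanoLuc samples, DiI standard),
  rectangular lanes, additive Gaussian camera noise, saturation warnings
  above 1% clipped in-lane pixels. No optical PSF, lane distortion or
  spectral bleed-through.
* **Plate reads:** expected signal = alleles × per-allele signal × a
  stage multiplier (default WT shape rises from 1 dpf to a 3 dpf peak and
  declines as yolk runs out); noise is lognormal with CV 0.2 by default —
  well-to-well error is multiplicative and strictly positive.
* **Gradient runs:** a linear density ladder from 1.11 to 1.03 g/mL over
  10 fractions, refractive indices generated by inverting the calibration
  (so the analysis round trip is exact to 1e-6), and a Gaussian reporter
  bump over fraction index (buoyant peak ≈ fraction 9 for the apoC2
  preset, dense peak ≈ fraction 4 for the mtp preset). Gradient-formation
  physics is not modelled.
* **Particles:** diameters from a Normal truncated at zero; the shipped
  defaults are the published wild-type fraction summaries (24.7 ± 5.6,
  29.0 ± 4.1, 34.9 ± 4.7 nm; n ≈ 170 per fraction).
* **Larva stacks:** uniform intensity within each region scaled to the
  requested viscera/trunk/head fractions, long frame = 3 × short before
  clipping, additive Gaussian noise. Frames are kept floating-point in
  memory (quantization to uint16 happens on TIFF export) so the noiseless
  closed loop is exact. The silhouette is stylized geometry, not anatomy.

Because the generators share none of the analysis code paths beyond the
deliberate calibration inverse, closed-loop recovery demonstrates the
*bookkeeping* of the pipeline — registration, binning, normalization,
exposure logic — not robustness to real-world artifacts (gel stretching,
uneven illumination, pigmentation, segmentation error), which remain the
user's responsibility.

## Problem sizes and tolerances

Monte-Carlo calibration checks run each test under its own null with fixed
seed families and compare rejection rates to 0.05 within 3 binomial
standard errors: Levene and Welch at 2000 replicates, Tukey and
Games–Howell family-wise error at 1000, the bootstrap two-way test at 500
replicates with B = 599. Bootstrap interval coverage is checked at 90%
nominal over 500 simulated datasets. Closed-loop gel recovery is asserted
at 1% absolute with ≥ 100 px per LU (discretization dominates below
that), and registration invariance is checked between 90 and 120 px
standards. These sizes were chosen to make the binomial bands tight enough
to detect real miscalibration while keeping the default suite quick to
run.

## Known limitations

* Electrophoresis assumes straight, undistorted lanes; there is no
  correction for gel stretching or smile.
* The ZM fraction is a catch-all (chylomicrons, aggregates, intracellular
  ApoB); the package classifies it but cannot resolve its constituents.
* The robust two-way bootstrap is the trimmed-means flavour only; other
  robust location estimators are not offered.
* Masks, lane bounds and origins are inputs; no image segmentation is
  attempted.
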
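# Methods

This note documents the models and numerical conventions behind `petex`,
the design decisions taken where the underlying dual-timepoint protocol is
underspecified, and what the synthetic-phantom validation does and does
not demonstrate.

## Coordinate and volume model

Volumes are axis-aligned 3D grids (NIfTI-1 on disk) with anisotropic
voxel spacing; the physical centre of voxel `(i, j, k)` is
`origin + (i, j, k) * spacing`. Oblique orientation matrices and DICOM
ingestion are out of scope. The tumour VOI is a binary mask drawn on CT
and mapped onto the PET grid by nearest-neighbour lookup at PET voxel
centres, assuming perfect co-registration; this preserves binarity and is
idempotent when the grids already coincide. The mapped-mask centroid can
move by at most half a PET voxel diagonal.

## Intensity pipelines

Each scan feeds two intensity streams:

* **Decay-corrected activity** (`roi_*` features): measured activity
  concentration multiplied by `2^(Δt/T½)` with Δt the injection-to-scan
  delay and T½ = 109.77 min for ¹⁸F. Per-scan actual times are used, not
  nominal protocol times.
* **SUV** (`suv_*` features): `SUV = c / (A·2^(−Δt/T½) / W)` with A the
  injected activity and W the body weight in grams (tissue density
  1 g/ml). SUV is decay-corrected by construction.

Within one scan these streams differ by a positive scale factor only, so
scale-invariant statistics (skewness, kurtosis, CV, entropy, energy)
coincide between the two blocks; both are reported because the catalogue
enumerates them separately.

**Quantization.** VOI intensities are resampled to 64 equally spaced bins
spanning the VOI min–max of that scan:
`bin(v) = 1 + floor(64·(v−vmin)/(vmax−vmin))`, maximum clamped to bin 64,
constant VOIs collapsing to bin 1. Edges are recomputed independently per
scan and per timepoint (no cross-timepoint harmonisation) — the most
literal reading of a per-VOI resampling protocol. Consequence: every
binned feature is invariant under positive affine intensity maps of a
single scan.

**Filters.** Gaussian smoothing is parameterised by FWHM with
`sigma = FWHM / (2√(2 ln 2))`, per-axis in voxels so kernels are
isotropic in millimetres. The Laplacian-of-Gaussian is implemented as
Gaussian smoothing followed by the exact discrete Laplacian
`Σ_axes (f(v+e) − 2f(v) + f(v−e)) / spacing²`: a sampled
second-derivative-of-Gaussian kernel is not DC-free at the sub-voxel
sigmas used here (1.5–2.5 mm against 4.7 mm voxels) and would respond to
constant volumes. All filters use the zero-flux reflect boundary, which
conserves total mass and maps constants to constants exactly. LoG
response entropies filter the *full* volume, then extract the VOI,
re-quantize to 64 bins and take the histogram entropy; filtering a masked
region alone would manufacture edge response.

Note on the LoG entropies: because each scale's response is re-quantized
to its own range, the entropy is a *shape* statistic of the response
histogram, not an amplitude statistic; it need not fall monotonically
with scale even though the response amplitude does. The test suite
checks the amplitude monotonicity (response SD strictly decreasing in
sigma on seeded white noise) and the entropy bounds.

## First-order features

Population moments (divisor N); kurtosis non-excess (Gaussian → 3);
percentiles by linear interpolation between order statistics. Degenerate
definitions never raise: a zero-variance VOI reports skewness/kurtosis 0
and CV 0, a zero-mean VOI reports CV as NaN, and every such case is
carried in a per-feature flag map through the pipeline (flagged-NA
propagation; one pathological lesion cannot abort a cohort run).
Constancy is detected from the exact min = max comparison so a constant
array cannot leak an ulp-sized spurious variance.

SUVpeak uses the 1 cm³ sphere convention (radius 6.2 mm), built in
physical units on the anisotropic grid and clipped to the VOI. TLG is
exactly `SUVmean × MAV`. Effective diameter is the diameter of the
equal-volume sphere, `d = (6·MAV/π)^(1/3)`.

## Texture matrices

Grey levels are the 1-based bin indices 1..64. All entropies are base 2
with `0·log 0 = 0`.

* **Directions.** Seven directions — the 3 axes, 3 face diagonals and the
  body diagonal: (1,0,0), (0,1,0), (0,0,1), (1,1,0), (1,0,1), (0,1,1),
  (1,1,1) — the canonical 7-element reduction of the 13 unique 3D
  directions. GLCM/GLDM use offsets `d × direction` for distances
  d ∈ {1, 2} (14 matrices); features are computed per matrix and averaged.
  GLRLM uses the 7 directions at unit step (runs are contiguous by
  definition). GLSZM and NGTDM are orientation-free and computed once.
  Matrices with no valid pair (VOI too thin along an offset) are excluded
  from the average; a family whose matrices are all empty is reported as
  flagged NaN. The direction set is closed under axis permutations and
  inversion (the symmetry regression-tested), but not under 90° rotations,
  which map face diagonals to anti-diagonals outside the set.
* **GLCM** is symmetric by construction (each ordered pair increments the
  cell and its transpose). "Difference variance" is the second moment of
  the difference histogram about zero, `Σ d²·p_d` — the definition forced
  by the identity with contrast; "homogeneity" is the inverse difference
  moment `Σ P/(1+(i−j)²)`. Information measures of correlation use
  base-2 entropies throughout (`IMC2 = √(1 − 2^(−2(HXY2−HXY)))`).
  A zero-variance marginal reports correlation 0 with a flag.
* **GLDM** here is the grey-level *difference* histogram of the same voxel
  pairs (not the pyradiomics dependence matrix). By construction
  GLDM mean ≡ GLCM dissimilarity, GLDM contrast ≡ GLCM contrast ≡ GLCM
  difference variance, and GLDM entropy ≡ GLCM difference entropy; these
  identities are enforced to 1e-9 in the validation suite.
* **GLRLM** runs are maximal same-bin sequences along a direction,
  terminated by VOI gaps; `Σ_j j·r(i,j)` equals the VOI voxel count in
  every direction (conservation-tested). The non-standard "intensity
  variability" and "run length variability" are the population variances
  of the grey-level marginal (over all 64 levels) and the run-length
  marginal (over observed lengths) of the run counts.
* **GLSZM** zones are 26-connected components of equal-bin voxels
  (configurable to 6); `Σ_j j·z(i,j)` equals the VOI voxel count. The two
  "variability" features mirror the GLRLM convention.
* **NGTDM** follows the Amadasun–King definitions with 26-neighbourhoods
  intersected with the VOI; voxels without any in-VOI neighbour are
  excluded, coarseness is `1/(ε + Σ pᵢsᵢ)` with ε = 1e-12 capped at 1e12,
  and single-level tables report contrast/busyness/complexity/strength 0
  by the 0/0 := 0 convention.

Every optimized builder is tested for exact count-level equality against
a naive triple-loop/flood-fill oracle on 200 random 4×4×3 VOIs.

## Model-based (fractal) features

All surface estimators work on the VOI bounding-box subvolume with
intensities rescaled to [0, 63]; voxels outside the VOI inside the box
are replaced by the VOI mean so the mask silhouette itself contributes no
roughness (and the flat-field limits below hold for arbitrary mask
shapes). The box is padded to a multiple of the 8-voxel window by edge
replication and tiled with non-overlapping windows, one local estimate
each.

* **Differential box counting**: per window and box size s ∈ {2, 4, 8},
  columns of s×s×s voxels count intensity boxes of height
  `h = s·64/8`: `n_r = ceil(max/h) − ceil(min/h) + 1`; FD is the
  least-squares slope of `log N_s` vs `log(1/s)`. A flat field gives
  exactly 3; the construction bounds estimates by 4. `fd_mean`/`fd_sd`
  are the window mean and population SD; `fd_inverse = 1/fd_mean`
  exactly.
* **Lacunarity**: gliding-box mass statistics `M₂/M₁² − 1` on the
  zero-filled masked intensities, averaged over the box-size ladder;
  scale-invariant, 0 for a constant field.
* **Blanket (Peleg) dimension**: upper/lower blankets via iterated ±1
  6-neighbour dilation/erosion, area `A(e) = Σ(u_e − l_e)/(2e)` for
  e = 1..5, FD = 3 − slope of `log A` vs `log e`, averaged over the same
  window grid. Flat field → exactly 3.
* **Hurst exponent**: half the log-log slope of the isotropic variogram
  (mean squared increment vs physical lag distance, lags 1–4 voxels per
  axis, pooled across axes, VOI-interior pairs only). Chosen over
  rescaled-range because it is the standard image-field estimator; a
  constant VOI returns 0 with a flag. The estimator recovers H = 0.5 on
  spectrally synthesised fractional-Brownian-like fields within ±0.1
  (50 seeds).

## Synthetic paired phantoms

The generator emulates the study conditions the analysis assumes: 54
patients split 30 benign / 24 malignant, PET grid 4.7 × 4.7 × 3.27 mm,
scans at 101.5 and 251.7 min post-injection of 350 MBq in a 70 kg
patient, 6 mm FWHM post-smoothing. Per patient: an ellipsoidal tumour
with uniformly drawn semi-axes (default 10–30 mm, spanning roughly
4–113 cm³ — the scale of the reported volume range), multiplicative
lognormal heterogeneity `base · exp(0.4 · field)` with the field a
unit-variance Gaussian random field of 12 mm correlation length
(smoothed white noise, variance renormalised by the kernel L2 norm),
base uptake 2.0 SUV on a 0.2 SUV background.

Kinetics are deliberately minimal — the analysis measures differences,
not kinetics: benign tumours wash out multiplicatively (late = w × early,
default w = 0.8); malignant tumours intensify focally (hottest decile of
tumour voxels × g, default g = 1.5), which raises SUVmax and skewness
without moving the bulk. Uptake is expressed on the SUV scale and
converted to activity at scan time through the physical decay factor, so
the SUV pipeline recovers the uptake field exactly; heteroscedastic
Gaussian noise with variance `κ · activity · 2^(Δt/T½)` (κ = 20 Bq/ml)
mimics the count loss of later scans (later scans are noisier in SUV
units by ≈ 2^(ΔΔt/2T½) ≈ 1.6×). Noise is applied before the 6 mm
smoothing. Everything is deterministic given the master seed, with
per-patient child streams.

What the phantoms do **not** model: tracer kinetics beyond the
multiplicative factor, sinogram Poisson statistics and OSEM
reconstruction, partial-volume effects beyond the smoothing, anatomical
background structure, segmentation variability (the mask is shared by
both timepoints, as in the CT-segmentation workflow). Passing phantom
tests therefore demonstrates the correctness and calibration of the
*pipeline*, not clinical reproducibility of any cohort median.

## Statistics

Per feature and group (all / benign / malignant, groups under 5 complete
patients skipped): related-samples Wilcoxon signed-rank, two-sided.
Zero differences are discarded (classical behaviour; Pratt handling
available via `zero_method="pratt"`); ties mid-ranked. For tie-free
samples of n ≤ 25 the exact null distribution is used (convolution of
rank generating functions — equivalent to enumerating all 2ⁿ sign
assignments); larger or tied samples use a normal approximation with
tie-corrected variance and continuity correction. The correction keeps
the two branches within 0.01 absolute p of each other at the n = 25
switchover (measured max ≈ 0.007); without it the gap reaches ≈ 0.015.
The exact branch's attainable two-sided level at n = 20 is 0.0484,
which is what "nominal 5%" means operationally for the calibration
suite.

Spearman correlation uses mid-ranks and the two-sided t approximation
(via scipy). The direction arrow is the sign of the *median paired
difference*, set only when p < 0.05; ties resolve to "none". No
multiple-testing correction is applied — each of the 99 features is
tested at the nominal level, and the report states the number of tests
performed so the family-wise exposure is visible.

ICC(2,1) — two-way random effects, absolute agreement, single measure —
is computed from the mean-squares decomposition
`(MS_R − MS_E) / (MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)` and
cross-checked against `pingouin.intraclass_corr`'s ICC(A,1) row in the
test suite. Zero between-subject variance reports NaN.

## Validation suites and problem sizes

The long-running checks use deliberately small phantom geometries chosen
as desk-scale study conditions:

* **Type-I calibration**: 600 independent null cohorts of n = 20
  (washout and gain factors 1, late scan time set equal to early so the
  two timepoints are exchangeable — with unequal scan delays the noise
  levels differ and nonlinear features such as SD and entropy would have
  genuinely different means, i.e. the null would be false, not
  miscalibrated). Grid 24 × 24 × 24, semi-axes 15–18 mm: large enough
  that the VOI bounding box always spans at least two fractal windows,
  so the windowed fd_sd has a sampling distribution. Each
  intensity-derived feature's rejection rate at p < 0.05 must fall in
  0.05 ± 0.025. The two mask-derived features (MAV, effective diameter)
  are excluded: the shared mask makes their paired differences
  identically zero, so they have no null distribution to calibrate.
* **Parameter recovery**: 20 cohorts at the full default conditions
  (n = 54, w = 0.8, g = 1.5, κ = 20): the benign subgroup must show a
  significant SUVmean decrease and the malignant subgroup a significant
  SUVmax increase in ≥ 90% of cohorts.
* **Oracle equivalence / identity / degenerate suites**: described above.

## Known limitations

* Cohort medians of the texture features depend on the exact direction
  set, bin edges and estimator variants of the original in-house
  software, which are not fully specified; the implemented identities
  and invariances hold for any consistent choice, but numeric medians of
  real cohorts are not reproducible by construction.
* The Hurst estimator is a variogram slope; published values above 1 for
  this feature family imply a nonstandard estimator, so numeric
  comparability is limited to ordering/association, not magnitude.
* "FD: SD" is the window-wise SD of local estimates (not the regression
  residual SD), and the blanket dimension is windowed and averaged,
  matching the "mean" naming.
* The GLRL/GLSZM "variability" features have no canonical published
  formula; the marginal-count variance reading is a documented choice.
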
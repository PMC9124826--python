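# Methods

## Coordinate contract

All metrics operate on world coordinates in mm. A `VoxelGrid` carries
shape, per-axis spacing, origin, and a 3×3 orthonormal direction matrix;
voxel indices are 0-based and a voxel's world position is its **center**
(`index_to_world(0,0,0)` equals the origin exactly). Using centers makes
every metric invariant under joint integer-voxel translation of both masks
and under the choice of where the grid starts. Masks entering a pairwise
metric must share a grid (shape equal, affines within 1e-4); resampling is
never implicit — `resample_to_grid` (nearest-neighbor through the affine
composition) exists for callers who decide co-registration onto one grid is
legitimate. NIfTI-1 is the mask format; the affine is honored as stored
(spacing = column norms, orientation = normalized columns), with no RAS/LPS
assumption beyond it. Note that the NIfTI header stores the affine in
float32, so world coordinates survive a write/read round trip only to about
1e-5 mm — far below any tolerance used here.

## Metrics

- **Volume** = voxel count × voxel volume; computed in mm³, reported in
  cm³. Reports round half-away-from-zero (1 decimal for volumes and
  distances, 2 for Dice), the convention of the clinical tables this
  pipeline reproduces; values are first snapped to a fine decimal grid so
  binary floating-point representation cannot flip a decimal tie
  (mean(17.5, 17.6) = 17.549999...997 must round to 17.6).
- **Center of gravity** = arithmetic mean of foreground voxel-center world
  coordinates (computed as the index-space mean pushed through the affine,
  which is identical because the map is affine). Undefined on empty masks —
  an explicit error, never a sentinel.
- **Dice** = 2|A∩B| / (|A|+|B|) over voxel index sets; since grids are
  shared this equals the volume formulation exactly.
- **Hausdorff** is taken over the **full voxel sets** (solid objects), not
  surfaces and not a percentile variant: the directed distance is
  max over a∈A of min over b∈B of ‖a−b‖ on voxel centers, and the symmetric
  value is the max of the two directions. For solid objects of equal
  topology a surface variant would usually coincide, but the solid-set
  definition is the one implemented and tested. Efficient evaluation uses
  `scipy.ndimage.distance_transform_edt` of each mask's background with the
  grid spacing as sampling — exact for axis-aligned anisotropic grids, and
  valid for any orthonormal orientation because rotations preserve
  Euclidean distance. The O(n²) brute-force double loop lives in the test
  suite and the two must agree to floating-point precision on random pairs.

Empty-mask policy: volume of an empty mask is 0; CoG, Dice (both empty) and
Hausdorff raise explicit errors. Post-resectional "0.0 cm³" residuals are
table entries, not mask comparisons, so they never reach the pair metrics.

## Extent of resection

GTR ⟺ residual volume on the last intraoperative US ≤ ε, with ε = 0 by
default because the reference cohort records exact zeros; ε is exposed
(`--epsilon`) to absorb rounding when residual volumes come from masks
rather than a table. "Extension of resection" means a nonmissing
intraoperative residual volume (the US finding that triggered further
resection). US/MRI concordance is the fraction of cases where both
modalities agree on residual presence at the same ε; discordant cases are
reported as discordant, never resolved by a priority rule. Exclusions are
data-driven flags with reason strings, logged when applied, and an excluded
record contributes to no statistic of that analysis.

## Statistics

- **Summaries**: sample SD (n−1); median = midpoint of the central order
  statistics; quartiles by linear interpolation.
- **Paired differences**: b − a over pairwise-complete pairs. Both the
  median difference and the median |difference| are reported: the former
  lets positive and negative per-case differences cancel, the latter is the
  magnitude summary.
- **Wilcoxon matched-pairs signed-rank** (authored here): zero differences
  are discarded before ranking (Wilcoxon's original method; Pratt's
  zero-rank variant is available via `wilcoxon_zero_policy: pratt`, with
  the variance and tie corrections computed over the nonzero ranks as in
  standard implementations). Absolute differences receive average ranks
  under ties; W = min(W⁺, W⁻). When there are no ties and effective
  n ≤ 20 (configurable, capped at 25) the two-tailed p is exact, from the
  full null distribution of W⁺ over all 2ⁿ sign assignments — computed by
  dynamic programming over the rank generating polynomial, which yields the
  identical distribution without enumerating 2ⁿ vectors; a literal
  enumeration oracle backs this in the tests. Otherwise a normal
  approximation with tie correction (−Σ(t³−t)/48 on the variance) and a
  0.5 continuity correction toward the mean is used.
- **D'Agostino–Pearson**: the K² omnibus (squared standardized skewness +
  squared standardized kurtosis against χ²₂), via `scipy.stats.normaltest`;
  n ≥ 8 enforced, constant data rejected.
- **Spearman**: Pearson correlation of average-rank vectors; p from the
  t-approximation with n−2 df. An exact permutation p (full enumeration of
  n! orderings) is available behind a flag for n ≤ 10.
- The reference cohort's published p-values cannot be reproduced from the
  rounded per-case table (they depend on the source system's unrounded
  segmentation volumes), so the pipeline reports its own p-values and the
  tests assert only qualitative agreement: paired volume comparisons and
  Dice–volume correlations non-significant at α = 0.05.

## Synthetic phantoms

No public archive provides co-registered MRI / intraoperative-US tumor mask
pairs, so validation uses phantoms whose MRI→US difference is composed of
exactly the three ingredients that separate the modalities in practice:
a rigid translation (brain shift), a smooth elastic deformation (tissue
distortion and probe pressure), and boundary segmentation noise (observer
variability at the margin).

- **Base object**: digitized irregular ellipsoid — a ball whose radius is
  modulated by a random smooth low-order function of direction (linear plus
  centered quadratic forms in the direction cosines, normalized to unit
  peak), scaled by `shape_irregularity` (default 0.15). Band-limited on the
  sphere, so the boundary stays smooth at any resolution.
- **Warp**: inverse mapping with nearest-neighbor sampling (masks stay
  binary; no thresholding ambiguity). The displacement is the rigid
  translation plus a Gaussian-smoothed white-noise vector field
  (correlation length `elastic_sigma_mm`, default 6 mm; peak magnitude
  `elastic_amp_mm`, default 1 mm). A translation by integer voxel multiples
  with zero elastic amplitude reproduces the rolled base mask exactly.
- **Noise**: each surface voxel (6-connectivity boundary, both sides) flips
  with probability `boundary_noise_prob` (default 0.05 for single phantoms,
  0.03 in cohort generation).
- **Determinism**: one integer seed per spec; all draws flow from a single
  `numpy` generator per call; no global state. Objects that touch the grid
  boundary raise a generation error rather than being silently clipped.

Default phantom grid: 96³ at 0.5 mm isotropic. Cohort generation auto-sizes
a centered cube grid per case (0.5 mm spacing, coarsened in 0.05 mm steps
once more than 128 voxels per axis would be needed) because the largest
tumors in the emulated volume range (up to 95 cm³, radius ≈ 28 mm) cannot
fit a 96³ half-extent of 24 mm together with a shift.

Cohort marginals emulate the reference study's structure: log-normal tumor
volumes (median 16.3 cm³, σ_log 0.89, clipped to 0.5–95 cm³), log-normal
shift magnitudes with isotropic random directions (mean 3.9 mm, σ_log 0.58,
clipped to 0.25–13 mm — direction isotropy is a modeling choice; no
per-case direction data exists), STR fraction 10/28 with log-normal
residuals (median 2.1 cm³), and extension-of-resection probability 4/18
among complete resections. Metric columns of synthetic records are always
*computed from the generated masks*, never sampled, so synthetic cohorts
are internally consistent with actual geometry. What the phantoms do not
emulate: ultrasound speckle or any intensity data, biomechanically
realistic deformation fields, and multi-focal or cavity-containing tumor
shapes — passing phantom tests therefore demonstrates metric and pipeline
correctness, not segmentation performance on real images.

## Problem sizes

Tests and the acceptance script use sizes chosen for a single-CPU desk run:
brute-force Hausdorff oracles on 50 random pairs of ≤ 500 voxels,
translation-recovery on 20 phantoms at 96³, Wilcoxon calibration on 200
simulated null cohorts of n = 30, and a 10-case end-to-end synthetic
pipeline run. The cohort reproduction itself is a 31-row table and runs in
well under a second.

## Known limitations

- Hausdorff on full voxel sets is what is implemented; consumers expecting
  the (more noise-robust) 95th-percentile surface variant will see larger
  values on noisy masks.
- The exact Wilcoxon route requires tie-free absolute differences; data
  recorded at coarse precision (ties) always takes the corrected normal
  approximation, whose small-sample accuracy is the usual ±0.02 around the
  exact p at n ≈ 15.
- Nearest-neighbor warping quantizes sub-voxel translations, so a phantom's
  realized shift differs from the requested one by up to half a voxel
  diagonal; tolerances in ground-truth recovery are stated in voxel
  diagonals for this reason.
- GTR/STR classification trusts the recorded residual volumes; it does not
  re-segment or cross-check against masks.
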
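# Methods

This note records what `pethotspot` computes, the conventions and
defaults it fixes where several reasonable choices exist, and what the
synthetic experiments do and do not demonstrate.

## Geometry and coordinates

Volumes are axis-aligned 3D grids of SUV with per-axis spacing in mm.
Voxel indices are 0-based `(i, j, k)`; world coordinates refer to
voxel centers, `world = origin + index · spacing`. Every distance in
the package is Euclidean in mm, so anisotropic voxels are handled
correctly. Only NIfTI-1 I/O is provided; inputs are assumed to be in
SUV already. Orientation metadata beyond spacing/origin is ignored:
all extracted features are rotation-covariant distances, ratios, or
intensity statistics, so any consistent axis convention yields the
same values.

## Segmentation

The metabolically active lesion is the set of seed-VOI voxels at or
above a fixed fraction (default 0.40) of the maximum SUV *inside the
seed*, i.e. the threshold is lesion-relative, not image-global.
By default the mask is restricted to the 26-connected component
containing the maximum voxel. Morphological closing with a ball of a
physical radius (default 2× the largest voxel spacing; 0 disables)
can swallow cold necrotic interiors into the VOI. The closing radius
must exceed the cavity radius to fill it — the necrosis experiments
below use 10 mm against an 8 mm core for that reason. Components use
26-connectivity; boundary voxels use 6 (face) adjacency so the
boundary is a tight one-voxel shell; voxels on the grid edge count as
boundary.

Derived geometry: `MTV = voxel count × voxel volume` (exact),
centroid = unweighted mean of in-mask voxel centers (the hot-spot
features describe the *shape-relative* position of the hot spot, so
the centroid is deliberately not intensity-weighted),
`R_eq = (3·MTV/4π)^{1/3}`.

## Hot-spot location

*SUVmax*: the in-mask voxel with maximal SUV. Ties are broken by the
smallest linear index in C order, deterministically, and flagged.
Note that an argmax is intrinsically sensitive to voxel noise — a
single flipped voxel moves the location by one voxel — which is
exactly why the peak-based variants exist.

*SUVpeak*: for every in-mask candidate center, the mean SUV over all
image voxels whose centers lie within `r = (3V/4π)^{1/3}` of it
(6.20 mm for the conventional 1 cm³ sphere); the candidate maximizing
this mean wins. The sphere is anchored in the lesion but averages
over the whole image (the usual peak-uptake convention); near the
image border the mean runs over the in-image voxels only. Implemented
as a direct correlation with the sphere-indicator kernel, so it equals
the brute-force double loop to float precision.

*Small-lesion fallback*: when the lesion diameter is below 12 mm
(default `2·R_eq`, optionally the maximum 3D Feret diameter), the
1 cm³ sphere does not fit and SUVpeak, NHOC_peak and NHOP_peak are
replaced by their SUVmax-based counterparts, with a flag recorded.

## NHOC and NHOP

`NHOC = ‖x_hot − centroid‖ / R_eq` — can exceed 1 for elongated
lesions. `NHOP = (distance from x_hot to the perimeter) / R_eq`.
Three perimeter representations are implemented:

* **mesh** (default): minimum distance to the vertices of the
  marching-cubes isosurface of the mask. The surface is subvoxel, so
  the estimate is nearly unbiased both deep inside the lesion and for
  hot spots on the surface (worst error ~0.03·R_eq on digital balls
  at 1 mm voxels).
* **edt**: the exact Euclidean distance transform read at the
  hot-spot voxel. Unbiased deep inside, but floored at one voxel for
  surface hot spots.
* **boundary_centers**: minimum distance to in-mask face-boundary
  voxel centers. Reads low by up to ~half a voxel diagonal (the inner
  corners of the boundary layer undercut the digitized surface); on a
  20 mm ball this bias alone reaches 0.05·R_eq, which is why it is
  not the default.

All three agree within about one voxel diagonal and are cross-tested.
For a perfect sphere NHOC + NHOP = 1; the deviation on real lesions
measures departure from sphericity. Under our definition NHOP cannot
exceed 1 by more than discretization slop; reported values above 1
from other software imply a different perimeter or normalization
convention and are not reproduced here.

`nSPD` is the 2D ancestor of NHOP: on the axial slice containing the
hot spot, the in-plane distance to the slice boundary normalized by
the radius of the equal-area circle.

## Preprocessing

*Gaussian postfiltering*: isotropic physical SD in mm (per-axis SD in
voxels = σ/spacing), reflect padding. σ = 2/3/4 mm correspond to
FWHM = 2.355σ ≈ 4.7/7.1/9.4 mm (nominal "5/7/9 mm" descriptions of
such filters are rounded values).

*Resampling*: trilinear for intensities, nearest-neighbor for masks.
The output grid is aligned to the input origin (voxel-center
alignment) and covers the input extent; beyond the last voxel center
the edge value is extended. Deterministic and reproducible.

*Discretization*: fixed bin width over a fixed range, default 0 to
60 SUV in 192 levels, i.e. width exactly 60/192 = 0.3125 SUV
(displayed elsewhere rounded to 0.31). `level = min(G,
floor((v − lower)/width) + 1)`; out-of-range SUVs clamp into the end
bins so G is invariant.

## Texture features

GLCM: distance-1 co-occurrences over the 13 unique 3D directions,
both orderings counted (symmetric), restricted to in-mask pairs,
pooled into one matrix, normalized. Features: joint entropy in log10
and inverse difference moment `Σ p/(1+(i−j)²)`. GLRLM: maximal
equal-level runs per direction, 13 directions pooled;
`SRE = (1/N_r)Σ r(i,j)/j²`, `LRE = (1/N_r)Σ r(i,j)·j²`. GLSZM:
26-connected equal-level zones; `LGZE = (1/N_z)Σ s(i,j)/i²`,
`HGZE = (1/N_z)Σ s(i,j)·i²`. Gray levels `i` are the 1-based
discretization levels. Merged-direction pooling is one of several
aggregation conventions in circulation; it is the package's fixed,
documented choice (per-direction averaging is available by calling
the matrix builders with a single direction). All three families are
verified against brute-force enumeration oracles.

## Surface area and sphericity

`sphericity = π^{1/3}(6V)^{2/3}/A`. Two surface estimators: exposed
voxel faces (exact for boxes, overestimates oblique surfaces), and a
marching-cubes mesh with subvoxel smoothing — the binary field is
smoothed with SD 0.8 voxels before the 0.5 isosurface, which removes
the ~9 % staircase overestimate and recovers a digital ball's area to
<0.1 %. Because the two estimators err in opposite directions,
sphericity can marginally exceed 1 on near-spherical digitized masks.
Masks too thin to survive smoothing fall back to the raw binary mesh.

## Robustness statistics

Bland–Altman: differences are B − A with the order recorded; SD uses
the n−1 denominator; limits are bias ± 1.96 SD. Both absolute and
percentage-of-pair-mean differences are reported, plus bias and LoA
width normalized by the feature's mean magnitude so features on
different scales can be compared. Spearman correlations use average
ranks; the correlogram reports |r| ordered by complete-linkage
clustering on 1 − |r|; constant features are reported missing and
excluded from clustering. ICC is the one-way random-effects,
single-score, absolute-agreement form,
`(MSB − MSW)/(MSB + (k−1)MSW)`, computed from the closed-form ANOVA
decomposition; a fully degenerate table returns 0 with a flag.

## Survival statistics

Kaplan–Meier, log-rank and Harrell's C delegate to lifelines (ties in
feature score 0.5; a usable pair requires the earlier time to be an
event). The C-index is reported with higher-feature-means-earlier-
death orientation, so values below 0.5 indicate protective features.

*Maximally selected rank statistics*: every cutoff keeping both
groups ≥ `minprop` (default 0.10) of the cohort is scored with the
standardized log-rank statistic (hypergeometric variance, standard
tied-time handling); the maximizing cutoff (midpoint of the flanking
values) is selected. Unrestricted extremes make the standardized
statistic degenerate, hence the minprop floor (settable to 0). Note
the standardized statistic can legitimately peak at an unbalanced
split even when a balanced "gap" split separates the groups
perfectly — the selection maximizes significance, not balance.
Because the cutoff is optimized, the naive log-rank p-value is
anti-conservative; significance is therefore assessed by permuting
feature values over subjects (default 1000 seeded permutations,
`p = (1+B)/(n_perm+1)`). This is assumption-free and verified to be
calibrated (null rejection rate 0.044 at nominal 0.05 over 500
simulated cohorts); asymptotic approximations are deliberately not
used. The direction label compares the Kaplan–Meier medians of the
two groups, falling back to the sign of observed-minus-expected
events when a median is undefined.

Two-feature risk stratification counts each subject's unfavorable
feature states (0/1/2); the three pairwise log-rank tests are
Benjamini–Hochberg adjusted. Group comparisons of feature values use
the two-sided Wilcoxon rank-sum test (exact for small tie-free
samples, normal approximation with tie correction otherwise). Cox
regression is out of scope.

## Synthetic data

*Phantoms*: an ellipsoidal lesion (default spherical, 20 mm radius)
of plateau 5 SUV on 0.5 SUV background in a 57³ grid of 1 mm voxels —
odd-sized so the lesion center is a voxel center rather than
systematically half a voxel off. The hot spot is an additive gaussian
bump (amplitude 5 SUV, SD 3.5 mm) centered a fraction `f` of the way
from the center to the surface along a chosen direction; the bump is
confined to the lesion, which guarantees the rendered maximum tracks
the bump center. SUVmax ≈ 2× SUVmean, matching the magnitude relation
typical of advanced-NSCLC primary lesions. An optional cold core
(default 8 mm radius, 1 SUV) receives no bump, so the hottest voxel
sits on the core rim — the mechanism by which central necrosis pushes
the hot spot outward. Additive white gaussian noise, default SD
0.05 SUV: real PET noise is correlated at the ~5 mm resolution scale,
so the *independent per-voxel* fluctuation a white model may add on a
1 mm grid must be far smaller than regional noise, which this default
respects. What the phantoms do **not** model: tomographic
reconstruction and its correlated noise, partial-volume effects,
respiratory motion, scanner heterogeneity, irregular lesion shapes.
Passing phantom tests therefore demonstrates estimator correctness
and qualitative robustness ordering, not clinical effect sizes.

*Cohorts*: feature vectors drawn from per-feature normal
distributions (defaults match the magnitudes of advanced-NSCLC
feature tables); event times exponential with subject hazard
`h₀·exp(Σ β_f x_f)` (a hazard ratio h per SD corresponds to
`β = ln h / sd`); censoring by an exponential rate and/or an
administrative horizon (default 48 months, baseline median
~12.5 months). All randomness flows through one seeded generator per
call.

## Problem sizes and numerical conventions

The test suite and the acceptance script size their simulations to
what the statistics need: 5 noiseless phantoms for the displacement
sweep (the analytic-recovery check isolates estimator geometry; noise
response is measured separately), 25 instances per brute-force oracle
comparison, 25 noisy phantoms for the smoothing-robustness contrast,
40 cohorts of n = 100 for power/direction recovery, 500 cohorts ×
1000 permutations for null calibration, 500 subjects for ICC
parameter recovery. Floating-point oracle comparisons use 1e-10;
count comparisons are exact. All hot-spot ties break to the smallest
linear index; all seeds are explicit; reports serialize the resolved
configuration and are byte-reproducible under identical inputs.

## Known limitations

* The argmax-based SUVmax location carries irreducible single-voxel
  noise sensitivity; NHOC/NHOP inherit ±(voxel size)/R_eq jitter.
* Merged-direction texture aggregation is one convention among
  several; values are comparable within this package, not across
  software without checking the convention.
* The permutation p-value is exact only under exchangeability of the
  feature across subjects (i.e. under the null of no feature–survival
  association); it does not correct for testing many *features*.
* Whole-body multi-lesion aggregation of NHOC/NHOP is out of scope;
  features describe a single lesion.
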
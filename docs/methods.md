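# Methods

This note documents the models, parameter choices and numerical conventions
behind `iplconcord`, and what the simulation does and does not establish
about clinical data.

## Coordinate conventions

Voxel indices are 0-based `(i, j, k)` with axes x = left–right,
y = anterior–posterior, z = cranio-caudal; world coordinates are
`index × spacing` in mm; `k` indexes axial slices.  All modalities of one
case share a single analysis grid (default 48×48×26 voxels at 2×2×3 mm).
The nominal acquisition slice thickness (5 mm for PET-attached volumes,
3 mm for MRI) is carried as metadata; the coarser effective PET resolution
is modelled by the PSF (below), not by resampling.

## The phantom

**Anatomy.**  The prostate is an ellipsoid with fixed aspect ratio
1 : 0.85 : 1 (x : y : z) scaled to a target volume drawn log-normally
(median 31 cc, clipped to 21–54 cc — the descriptors of the emulated
clinical cohort).  The transition zone is an inner, slightly anterior
ellipsoid (60/55/85% of the gland's semi-axes); the peripheral zone is the
remainder.  Apex/mid/base are equal thirds of the cranio-caudal extent.
The voxelized volume differs from the requested one by a surface
discretisation term (≈1% at the default grid), not by one voxel.

**Dominant lesions.**  One focus per case (two with probability 0.3), as
ellipsoids with mild random anisotropy placed fully inside the gland
(bounded rejection sampling; an infeasible placement raises an error for
the first focus and silently drops a secondary one).  Relative volume is
log-normal (median 19%, clipped to 6–75%), SUVmax log-normal (median 8.2,
clipped to 1.9–21.4), Gleason scores drawn with the clinical strata
frequencies (6/7a/7b/8/9 ≈ 23/17/14/29/17%), PSA log-normal (median
15.4 ng/mL, 0.6–57.9).

**Uptake profile.**  Default is a Gaussian profile truncated at the lesion
support (the ellipsoid is the half-maximum isosurface): tracer uptake lives
in tumour tissue and falls off from the peak, which is what makes a
40%-of-SUVmax contour genuinely larger than an 80% one.  A uniform plateau
(`lesion_shape="ellipsoid"`) is available; with it every fractional contour
≥ the plateau/background contrast covers the whole lesion and the threshold
family degenerates.  The pre-blur peak equals the assigned SUVmax exactly.

**Satellite microfoci.**  Poisson-distributed (mean 1.2/case) deposits of
0.3–1.5% of gland volume with SUV 1.6–2.8 — above background but below both
the absolute SUV-3 cut and the 40% fraction of a typical lesion peak, and
below MRI visibility.  They exist because systematic biopsy regularly finds
tumour outside the imaged lesion; without them every biopsy-positive sector
lies inside the (margin-expanded) contour and simulated sensitivity pins at
100% for all thresholds.

**Imaging.**  PET = body background (SUV 0.5) + prostate background
(SUV 1.5) + lesion inserts, convolved with an isotropic Gaussian PSF
(default FWHM 6 mm — typical clinical PET resolution), plus additive
Gaussian noise (SD 0.1 SUV) truncated at zero.  MRI-like channels (T2W,
ADC, DCE) are piecewise-constant with the clinically expected contrast
direction (lesions hypointense on T2W/ADC, enhancing on DCE), optional blur
and 2% noise.  No reconstruction physics, no DICOM.

**Simulated readers.**  A "manual" contour is the true mask displaced by a
smooth random level-set field with RMS amplitude `observer_noise_mm`
(correlation length 6 mm); 0 mm reproduces the truth exactly.  The pipeline
uses 1.5 mm for PET readers and 2.5 mm for mpMRI readers — mpMRI delineation
is the less certain task.

**Determinism.**  Every case derives its generator from
`(cohort seed, case index)`; biopsy and observer noise use further derived
streams.  Identical seeds give byte-identical volumes and report files.

## Sector map and biopsy

Each region is divided into 12 sectors = side (left/right) × zone
(peripheral/transition) × three angular wedges of the mirrored half-plane
angle, a choice that is even, zone-aware and left/right symmetric; the
standard schematics do not prescribe an exact geometry, so the subdivision
is configurable.  Voxels are assigned by the same rule around the
per-region centroid, giving an exact partition of the gland; the schematic
polygons (a disc with an inner transition-zone ellipse, tiled by the same
side/zone/wedge rule) are the objects registration warps.

Biopsy cores are straight needles along the anterior–posterior axis:
12 systematic positions ({left,right} × {medial,lateral} × {apex,mid,base};
10/11-core guideline variants drop medial apex cores) plus one targeted
core through each imaging-visible lesion centroid.  A core traversing a
lesion detects it with probability `1 − exp(−path/λ)`, λ = 3 mm by default
— short intralesional paths (small foci) are missed more often, with
certain detection and certain miss available as limits.  Detected lesions
mark the sectors the core crossed *inside the lesion* positive (inheriting
the lesion's Gleason score); other sectors a core sampled become negative;
unsampled sectors are treated as negative for scoring by default (a sector
without a positive biopsy counts against the contour), with exclusion
available.

## Registration

One registration per axial level (section model; no 3D registration).  The
representative (middle) slice of each region supplies the prostate outline
(sub-voxel marching-squares contour).  Correspondence is anchored
anatomically: both outlines are resampled counter-clockwise from the
patient-right direction — the role the display orientation plays for a
human operator; a circular-shift search is available when no anchor is
trusted.  Stage one is a least-squares similarity fit (Umeyama solve with
reflection guard; scale absorbs the schematic/patient size difference).
Stage two is an interpolating thin-plate-spline displacement
(`scipy.interpolate.RBFInterpolator`, smoothing 0) on 16 control-point
pairs at matched arc-length fractions; the warp passes exactly through
every pair (residuals < 1e−9) and is the identity for coinciding outlines.
Sector transfer pulls each voxel centre back through the inverse warp
(fitted on swapped pairs; exact at control points) and inverse rigid onto
the schematic plane and looks it up in the sector polygons; a preimage that
falls outside all polygons is assigned to the nearest polygon, never
dropped.

## Contouring and scoring

SUVmax is taken over the whole prostate (a per-focus variant exists behind
a flag for multifocal ambiguity).  Contours are 26-connected components of
`{SUV ≥ threshold} ∩ prostate`.  Lesions enter the analysis once — imaged
volume ≥ 1 cm³ and SUV ≥ 3 (both bounds inclusive) — and every method and
threshold is then evaluated for that fixed lesion set, so per-threshold
means are paired; a lesion invisible at a tight threshold scores an empty
prediction rather than dropping out (dropping it makes mean sensitivity
non-monotone in the threshold through survivorship).

Margin expansion dilates by a physical ball (Euclidean distance transform
with anisotropic sampling), so 5 mm means 5 mm on every axis.  The 5 mm
margin is applied to the image contour before sectorization (default).
Applying it to the biopsy side as well is implemented (`margin_mode="both"`)
but not default: at 36-sector granularity on a 21–54 cc gland, dilating the
positive sectors' voxel support by 5 mm marks nearly every sector positive
and collapses the metrics — a sector-level reference has the margin's
tolerance built into its coarseness.

A sector is predicted positive on any overlap with the expanded contour
(`overlap_fraction` raises the required covered fraction).  Scoring uses
all 36 sectors by default; a case without a positive sector leaves
sensitivity undefined and is flagged, and undefined values are excluded
pairwise from aggregation (counts reported).  A voxel-level Dice against
the margin-expanded positive-sector volume is provided as a secondary mode.
Mean ± sample SD per method across lesions mirrors the clinical summary
layout; the best threshold maximises mean DSC, asserts concordance with
mean YI (discordance returns the DSC maximiser, flagged), and breaks exact
ties by YI then specificity.

## Statistics

Kolmogorov–Smirnov against a normal with the sample's own mean/SD (screen
only; constant samples are flagged and skipped), Kruskal–Wallis across
methods (all-tied data returns H = 0, p = 1), and point-biserial Pearson r
between stratum indicators and per-lesion DSC.  Volume strata are "at least
x%" indicators for x ∈ {5, 10, 15, 20}% — the labelling that matches an
accuracy advantage *for* large lesions.  No multiplicity correction by
default (the analysis is exploratory); Benjamini–Hochberg behind a flag.
No multivariate regression is attempted.

The factor-gradient replication uses a lightweight per-lesion generator
(`simulate_dsc_factor_cohort`): covariates from the phantom's clinical
distributions, with a 25% admixture of small non-dominant foci (1–5% of
gland volume) so the ≥5% indicator has both classes, and DSC following a
logistic volume response (floor 0.20, gain 0.60, midpoint 15% of gland
volume, width 3%, noise SD 0.08, clipped to [0, 1]).  The midpoint encodes
a threshold character of delineation accuracy — below the scanner's
partial-volume scale every lesion delineates poorly — and is placed at the
relative volume where the emulated clinical analysis located the accuracy
transition.  Under these settings the ≥15% indicator correlates with DSC
more strongly than the ≥5% one in ≈99% of replicate cohorts.

## Problem sizes

Default analyses use 48×48×26 grids at 2×2×3 mm, 30-case cohorts for the
threshold trade-off, 200 replicate cohorts of 33 lesions for the factor
gradient, and 50-seed Monte-Carlo for rigid recovery — sizes chosen so the
full suite and the acceptance script each run in minutes on one CPU while
keeping the Monte-Carlo standard errors well below the asserted margins.

## What passing does and does not show

The phantom demonstrates that the pipeline's machinery is correct (exact
oracles, partitions, monotonicities, calibrated test sizes) and that the
qualitative clinical pattern — sensitivity falling and specificity rising
along the threshold family, accuracy increasing with lesion volume —
emerges from minimal, explicit mechanisms (peaked uptake + PSF,
imaging-occult microfoci, path-length detection).  It does not reproduce
clinical metric magnitudes: those depend on the 35 unavailable patients,
the real sector geometry, reader behaviour and scanner physics.  In
particular the threshold with the highest mean DSC on the phantom defaults
(80%) is not asserted to match the clinically selected 70%: the optimum
moves with PSF width, uptake profile and margin handling.  Known further
limitations: straight biopsy needles, piecewise-constant MRI model, no
inter-observer reconciliation model (per-observer warps are exposed
instead), no DICOM I/O.
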
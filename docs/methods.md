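# Methods

## Coordinate frame and inputs

All geometry lives in a physical 2-D frame in millimetres: **x** increases
anterior → posterior, **y** increases caudal → cranial. Mask images (PNG
stacks or a NIfTI volume with time on the third axis) are mapped into this
frame with row 0 on the cranial side; an orientation flag
(`anterior_left` / `anterior_right`) says which image side faces the
sternum, so that downstream rules ("the anterior corner has smaller x") are
orientation-free. Any nonzero pixel is foreground. The first frame is
taken as end-expiration and the last as end-inspiration — the acquisition
runs between the two breath-holds — and both indices can be overridden per
subject.

Contours are traced at the 0.5 iso-level of the (largest connected
component of the) mask with marching squares, i.e. sub-pixel midpoints
rather than pixel edges, which removes most staircase bias from areas and
distances. Interior holes are discarded; component ties break by earliest
raster-scan order.

## Landmarks

1. **Orientation.** A direct algebraic least-squares ellipse fit to the
   outline vertices (principal axes of the vertex scatter as fallback when
   the algebraic fit fails, is non-finite, or is wildly eccentric). The
   major axis, taken with positive cranial component, defines the
   subject's cranio-caudal direction; its angle from +y is reported in
   (−π/2, π/2].
2. **Lung apex** — the vertex maximising the projection on the cranial
   major-axis direction; ties go to smaller x.
3. **Centroid** — the polygon *area* centroid (not the vertex mean; for
   "centre of gravity" of a region the area centroid is the defensible
   reading, and for dense contours the difference is negligible).
4. **Costophrenic angles** — among vertices whose major-axis projection is
   caudal to the centroid's ("the lower lung", an orientation-corrected,
   parameter-free cut), split into an anterior and a posterior side by the
   major-axis line through the centroid; each side's corner is the vertex
   farthest from the centroid. Ties break caudal-most, then smallest x.
5. **Diaphragm contour** — of the two boundary paths between the corners,
   the one not containing the lung apex, oriented anterior → posterior.
6. **Diaphragm apex.** The *raw* apex maximises perpendicular distance to
   the corner chord (ties to the smaller arc-length fraction; a flat
   diaphragm is flagged degenerate at fraction 0.5). Because the raw apex
   is unstable between consecutive frames, all distance outcomes use the
   *derived* apex: the median of the per-frame raw arc-length fractions,
   evaluated on each frame's diaphragm contour by linear interpolation.
   The median of an even count is the mean of the two central values.

Every rule above is deterministic; on ≥100 randomised phantom contours the
implementation agrees exactly with brute-force scans of the same
definitions (see `tests/test_acceptance.py`).

## Outcomes

Per frame: CC = ‖lung apex − derived diaphragm apex‖; AP = x-extent of the
contour (the ellipse minor axis is *not* used — the x-extent of the
orientation-normalised frame is stable when the fitted ellipse rotates
slightly between frames); lung area = shoelace area; DA = signed area
between the diaphragm polyline and the corner chord; DH = signed
perpendicular distance from the derived apex to the chord. DA and DH are
positive when the dome bulges toward the lung interior; a sign flip between
the two breath-hold frames (paradoxical inversion) is flagged rather than
hidden in a magnitude.

Per subject: ratios are end-inspiration / end-expiration; the CC-AP ratio
is CC ratio / AP ratio exactly. Corner displacements are net Euclidean
distances between the two breath-hold frames (the summed frame-to-frame
path length is exported separately as a jitter diagnostic; net displacement
is the quantity the expiration-vs-inspiration overlays depict). A nearly
flat expiratory dome makes DH/DA ratios meaningless, so they are flagged
undefined below configurable thresholds (|DH| < 0.5 mm, |DA| < 25 mm²)
instead of being returned as huge numbers.

## The respiratory phantom

The phantom is the package's verification instrument: a lung silhouette in
which every outcome has a closed form.

* **Body**: vertical walls a width W (= AP extent) apart, basal corners on
  a horizontal chord.
* **Apex cap**: half super-ellipse of height c and exponent q; area
  W·c·g(q) with g(q) = Γ(1+1/q)² / Γ(1+2/q).
* **Dome**: a power-law bump y = d·(1−(2s−1)²)^p over the chord; area
  W·d·f(p) with f(p) = √π·Γ(p+1) / (2·Γ(p+3/2)); DH = d exactly, and the
  dome apex sits at arc-length fraction 0.5 by symmetry.

The two exponents are what make the family expressive enough for measured
cohorts:

* p decouples dome **area** from dome **height**, so DA and DH ratio
  targets can be met simultaneously (a circular-segment dome cannot — its
  area is fixed by chord and height, forcing DA ratio ≈ AP×DH ratio, which
  real cohorts violate). The expiratory exponent is 1.5, chosen so the
  solved inspiratory exponents of all phenotype presets stay ≥ 1;
  exponents < 1 give the dome a vertical tangent at the corners, which is
  anatomically implausible and leaves a sub-pixel sliver that no raster
  can represent.
* q decouples lung **area** from the CC and AP extents. Measured cohorts
  expand area faster than CC×AP (the expiratory lung is wedge-like, the
  inspiratory lung columnar), so the generator solves for a pointier
  expiratory cap and a boxier inspiratory cap (q ∈ [1, 4], cap height
  fixed at 0.45 of the above-chord extent) by a monotone 1-D bracket
  solve; infeasible area targets raise an error stating the feasible band.

Given target ratios (CC, AP, DH, and optionally area and DA), the
end-expiration and end-inspiration geometries are solved exactly;
intermediate frames interpolate extents geometrically (only the end frames
enter ratios). The posterior-corner displacement target P is realised by
dropping the basal chord by √(P² − ΔW²) with the anterior corner fixed in
x; if P is smaller than the AP-driven widening ΔW the chord stays level and
the ground truth records the realised displacement. Ground truth always
reflects realised geometry, never the requested numbers.

Rasterisation marks a pixel foreground iff its centre lies inside the
polygon — the unbiased emulation of a manual segmentation (scan-fill
rasterisers that include boundary pixels inflate the region by a fraction
of a pixel along the whole perimeter, a +1.5 % area bias on a
half-disc-sized shape). The default grid registration puts the coordinate
origin on a pixel corner; the generator jitters the registration and a
rigid whole-series translation per seed, which is the only randomness —
ground truth is analytic.

Closed-form validation shapes are separate: `half_disc_validation_polygon`
bulges a half-disc (DA = πr²/2, DH = r) from the middle of a wider flat
base so the basal corners stay sharp right angles. Attaching a half-disc
directly to the walls creates vertical-tangent corners whose sub-pixel
sliver vanishes on any raster and drags the measured DA ~20 % low — a
property of the degenerate shape, not of the measurement.

**Defaults as study conditions.** Expiratory CC 140 mm, AP 120 mm, dome
height 30 mm (typical adult sagittal values), 15 frames, 512 contour
vertices, 1 mm raster. Phenotype presets carry the measured group means of
the three cohorts (healthy: CC 1.72, area 2.54, CC-AP 1.38, DA 0.91,
DH 0.82, posterior displacement 70.7 mm; normal-spirometry: 1.60 / 2.57 /
1.22 / 1.34 / 1.08 / 70.6; decreased-spirometry: 1.32 / 1.95 / 1.04 /
1.79 / 1.41 / 35.6); the `severe` preset is qualitative (CC ratio 1.0,
preserved chest-wall motion, strongly increased curvature, minimal
excursion) since only its CC behaviour is quantified in the literature.
Between-subject SDs (cc 0.15, ap 0.08, area 0.25, da 0.25, dh 0.20,
displacement 8 mm) are package choices — cohort studies report these only
graphically. Drawn DA and area ratios are clipped to the dome family's
feasible bands.

**Pulmonary-function link.** Simulated supine FVC, postural FVC drop
(ΔFVC = upright − supine), MIP and MEP are linear functions of the
subject's true CC ratio plus Gaussian noise, anchored to the cohort group
means and with noise SDs matching reported within-group spreads (≈10, 5,
24, 28 % predicted respectively). This is an explicit simulation
assumption, not an empirical claim: a single linear link understates
biological scatter, so the simulated Spearman correlation between CC ratio
and supine FVC (~0.9) is higher than typically measured (~0.65–0.7). Tests
therefore assert only the sign structure and a conservative lower bound,
not the exact correlation.

**What the phantom does not emulate**: MRI intensities and noise, the
heart (relevant for left-lung segmentations), segmentation-rater shape
bias, through-plane motion, and frame-selection ambiguity. Passing tests
show the *measurement chain* is correct and well-conditioned at 1 mm
resolution; they cannot certify segmentation quality on real images.

## Statistics

* **ICC** — two-way mixed-effects, absolute agreement, single measurement:
  (MSₛ − MSₑ) / (MSₛ + (k−1)MSₑ + (k/n)(MSᵣ − MSₑ)) from the two-way mean
  squares; implemented directly (and cross-checked against an independent
  implementation in the tests). Constant matrices are flagged undefined.
* **Bland–Altman** — bias = mean(a−b), limits bias ± 1.96·SD(a−b).
* **Spearman** — average ranks for ties (scipy); constant inputs are an
  error, not a silent NaN.
* **Adjusted group comparison** — OLS of outcome on group indicators plus
  caller-chosen covariates (no automatic selection; age is the usual
  choice). The overall p is the joint F-test on the indicators; pairwise
  contrasts are tested at the Bonferroni level 0.05/3 ≈ 0.017. With two
  groups and no covariates this reduces to the pooled two-sample t-test
  (asserted to 1e-10 in the tests). Residual diagnostics (SD, skew,
  kurtosis, curvature of residuals vs fitted) are exported as numbers in
  lieu of eyeballing residual plots.
* **Subgroup rule** — normal spirometry iff supine FVC ≥ 80 % predicted
  and z ≥ −1.64; ΔFVC = upright − supine.

## Numerical choices and limitations

* Tie tolerances are absolute 1e-9 mm on projections/distances; landmark
  vertex matching uses 1e-6 mm.
* The ellipse fit is only an orientation device; its axes never enter an
  outcome directly.
* Problem sizes in the test-suite and the reproduction script (20 phantoms
  per preset, 100 ICC replicates, 200 regression replicates, a 53-subject
  cohort) were chosen so each check's Monte-Carlo error is well below the
  tolerance it asserts.
* Displacements inherit about half a pixel of corner-localisation noise
  per frame; DA/DH inherit chord-placement noise of similar size, which is
  why those ratios carry the widest single-phantom scatter (~2 %).
* The pipeline is 2-D and single-slice by design; it does not attempt
  volumetric diaphragm assessment, automatic lung segmentation, left-lung
  heart handling, or temporal smoothing beyond the median-fraction rule.
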
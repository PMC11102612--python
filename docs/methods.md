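# Methods

This note records the models, numerical choices and limitations behind
`cranioshape`.  It is written for a reader who wants to know *why* the
pipeline computes what it computes, and what a passing test suite does and
does not establish about real data.

## Geometry

**Meshes.** All surfaces are triangle meshes in millimetres.  STL files are
read through `trimesh` with duplicate-vertex welding at 1e-6 mm (STL stores
facets independently; welding is required for any neighbourhood query).
Enclosed volume uses signed-tetrahedron summation and requires a closed
mesh (every edge shared by exactly two faces); the absolute value is taken
so that a globally inverted orientation cannot flip the sign of an
intracranial volume.

**Smoothing.** Taubin λ/μ smoothing with uniform (combinatorial) Laplacian
weights, defaults λ = 0.5, μ = −0.53, 10 iterations.  The near-cancelling
inflate step keeps shrinkage low (sphere volume change < 2 % after 20
iterations in the tests), which matters because shrinkage would bias every
curvature magnitude upward.

**Principal curvatures.** At each vertex an osculating quadratic height
patch h(u, v) is fitted by least squares over the 2-ring neighbourhood, in
a tangent frame built from area-weighted vertex normals; the full first
fundamental form correction is applied, and k1 ≥ k2 are the eigenvalues of
the Weingarten map.  A quadric fit was chosen over discrete cotangent
operators because it is robust to the irregular triangulations produced by
non-rigid registration and converges against analytic surfaces (sphere
median scaled error ≈ 0.007, cylinder k1 within ~1 %, both asserted in the
tests).  Sign convention: outward normals, convex-outward regions positive
in k1 (a sphere has k1 = k2 = +1/R).  The opposite convention is one
`CurvatureField.flip()` away; both conventions exist in the clinical
literature, so the field records which one it carries.  Vertices with fewer
than 5 usable neighbours (only possible on pathologically coarse meshes)
fall back to their 1-ring average with a warning.

## Registration

Rigid alignment is Kabsch/Umeyama on the 8 standard cranial landmarks
(supra-orbital notches, infra-orbital foramina, porions, opisthion,
lambda), reflection-safe, with optional uniform scale.  Scale is off by
default: generalized Procrustes analysis standardises size later, so the
rigid stage only needs to bring surfaces into the template's frame.

Non-rigid ICP is the stiffness-regularised per-vertex-affine formulation:
each template vertex carries a 3×4 transform, data terms pull vertices to
their closest points *on the target surface* (exact point-triangle
projection, not nearest vertices), gated by a 60° normal-compatibility
test, and an edge-wise stiffness penalty ‖(X_i − X_j)G‖² is relaxed over
the strictly decreasing schedule (50, 20, 5, 2).  The output always has the
template's topology, which is what makes dense per-vertex shape statistics
meaningful.  Non-convergence within a stiffness step is a warning, not an
error — the next (softer) step usually absorbs it.

## Anthropometry

All frame-dependent measures are computed in a Frankfurt-aligned anatomical
frame derived from the subject's own landmarks: x along the inter-porion
axis, z along the (least-squares) Frankfurt-plane normal oriented towards
lambda, y = z × x anterior, origin at the porion midpoint.  This makes
every measure invariant to how the input meshes happen to be positioned
(asserted to ~1e-9 in the tests).

* **DIST** — Euclidean distance between the medial orbital landmarks
  LM1–LM2 (fronto-maxillary junctions), mm.
* **RATIO** — mean orbital height (|LM3−LM7|, |LM4−LM8|) over mean orbital
  width (|LM1−LM5|, |LM2−LM6|), dimensionless.
* **CI** — maximal width extent over maximal length extent in the
  anatomical frame, reported as a plain ratio (not ×100).
* **IFA** — a plane parallel to the Frankfurt plane is passed through the
  *midpoint* of the two supra-orbital notches (two points plus a
  parallelism constraint under-determine a plane; the midpoint rule is the
  documented interpretation); the single most anterior mesh vertex (max y,
  ties broken by larger z) is projected onto it and the angle subtended by
  the notches is returned in degrees.
* **ICV** — volume of the intracranial mesh in mL.

**Thin-plate splines.** The 3D interpolant uses the biharmonic kernel
U(r) = r with an affine part; control points are reproduced to < 1e-6 mm
and uniform scaling is an exact special case.  One sign subtlety is worth
recording: the 3D distance kernel is conditionally *negative* definite, so
the bending energy is the **negated** upper-left block of L⁻¹ — the
opposite convention from the planar r² log r spline.

**Sliding.** Semi-landmarks slide along contour tangents (central
differences along each 25-point orbital contour) to minimise bending energy
against a reference configuration, anatomical landmarks fixed.  The exact
quadratic minimiser is taken along the tangent subspace; an update that
would increase a subject's energy is rejected, and iteration stops early if
the cohort total stops decreasing — so the reported energy trace is
non-increasing by construction.  The reference defaults to the GPA mean,
recomputed each iteration (3 by default), rescaled to the mean centroid
size so the kernel lives on a physical scale.  Bending-energy sliding was
preferred to minimum-Procrustes-distance sliding because the orbital
contours are open curves with fixed anatomical anchors.

## The frontal-curvature profile

The area of interest is the midsagittal band from the glabella to the most
anterior point of the anterior fontanelle.  The midline path is the
intersection of the midsagittal plane with the vault, trimmed to the
*shorter* arc between the two landmarks (the forehead arc) and arc-length
parameterised; sections are 91 stations (numbered 0…90, honouring both
printed end labels) at equal **arc-length** spacing — chord-based spacing
would compress sections on strongly curved foreheads, which is exactly
where the signal lives.

A section averages k1 over surface samples whose arc-length projection
falls in its band, whose distance to the midsagittal plane is ≤ 10 mm
(half-width), and whose distance to the path is ≤ 1.5 × half-width.  The
last (tube) cutoff is a deliberate addition: without it, skull-base
vertices below the glabella project onto section 0 and contaminate it.
Because 91 bands over a ~100 mm path are narrower than the edge length of
any practical mesh, the band statistics are computed over a barycentric
resampling of the strip (midpoint subdivision until the sampling is finer
than the band, with the curvature field interpolated linearly *on the
surface*).  This decouples band occupancy from mesh resolution; a band
with genuinely no surface in it is still reported missing — missing
sections are flagged and skipped, never filled in.  `mean curvature on a
section` defaults to the mean of k1 (ridges are a k1 phenomenon); H =
(k1+k2)/2 is available via `measure="mean"`.

Group profiles are compared section-wise by the difference of group means
with a seeded bootstrap percentile interval (2000 resamples, 95 %); a
section is significant when its interval excludes zero.  **CURV** is the
mean over sections 2–31 by default; `curv_from_significant_sections`
implements the automatic alternative (average over the sections a
comparison found significant).

## Statistics

* **GPA** — centre, scale to unit centroid size, iterate rotations to the
  evolving consensus until the mean moves < 1e-10.  The consensus is
  initialised from the normalised average (not the first configuration) so
  that already-aligned data is a strict fixed point.  Convergence is slow
  only for near-maximally dissimilar shapes, where a warning is emitted.
* **Permutation MANOVA (RRPP)** — sequential (type-I) sums of squares for
  group, age, group:age on the multivariate responses; per term,
  F = (SS_t/df_t)/(SS_res/df_res) and R² = SS_t/SS_total; p-values permute
  the residuals of the reduced model excluding the term.  Under the null
  the empirical type-I error at α = 0.05 sits in [0.03, 0.07] over 500
  replicates and the p-values pass a KS uniformity check (asserted).
* **Pairwise tests** — statistic = distance between group means, labels
  permuted within the pair; responses are first residualised on age when
  age is supplied.  Unadjusted p-values are returned (a Holm helper is
  provided) because the multiple-testing policy belongs to the caller.
* **Age residualisation** — local-linear lowess with tricube weights,
  span 0.75, no robustness iterations.  It captures linear trends exactly;
  on strongly curved monotone trends a small edge bias remains in the
  residuals (|Spearman ρ| up to ~0.2 in the tests) — an inherent property
  of the span, recorded rather than hidden.
* **Two-way ANOVA** — type-II sums of squares for residual ICV on sex ×
  group; the R² decomposition sums to one only in balanced designs, and an
  empty cell drops the interaction with a warning.
* **Disparity** — per-group mean squared distance to the group centroid in
  score space; the per-subject squared distances feed pairwise Wilcoxon
  rank-sum tests with Bonferroni adjustment, with an optional age split
  (e.g. 10 months).

## Classifiers

* **ROC** — thresholds at midpoints of consecutive observed values;
  trapezoid AUC (identical to tie-corrected Mann–Whitney pair counting,
  asserted exactly against brute force); cutoff maximises Youden's J, ties
  resolved toward specificity; when the positive class has *lower* values
  the score is auto-flipped and the flip recorded (`flip="none"` restores
  the raw orientation, under which sensitivities below 0.5 can appear).
* **KNN** — stratified 80/20 split, z-scoring on training statistics, odd
  K in 1…15 (odd avoids vote ties), smallest K attaining the best test
  accuracy.  The reported accuracy is the best over the K grid on the same
  test split — the optimistic selection of the original procedure, kept
  deliberately.
* **HCPC** — PCA on standardized features (axes retained at 95 %
  variance), Ward linkage on the retained scores, cluster count q chosen
  to maximise the relative inertia loss, i.e. minimising i(q)/i(q−1) over
  q in 3…min(10, n/3).  The search starting at 3 follows the classical
  HCPC implementations; near-coincident raw data degenerates to q = 2 with
  near-zero inertia loss.  Cluster-to-diagnosis confrontation uses a
  maximum-agreement (Hungarian) matching.

## The synthetic cohort

The generator is the package's study population.  Each vault is an
ellipsoid (half-axes 65 × 78 × 58 mm at the 220-day reference age) on a
fixed icosphere parameterisation (subdivision 4, 2562 vertices — a
resolution that keeps a ~200-subject cohort generable in minutes on one
CPU), deformed by interpretable knobs:

* a **frontal boss** (all groups): a broad anterior radial bulge giving
  infants their forehead prominence;
* a **midline crease**: a radial ridge `A·exp(−|azimuth|/σ_az)` whose
  non-smooth apex runs up the metopic line from the glabella, fading with
  elevation over σ_el.  MR is a narrow, glabella-limited crease
  (A = 0.045 ± 0.007, floor 0.015, σ_az = 0.18, σ_el = 0.25); TG a wide,
  strong one (A = 0.060 ± 0.008, σ_az = 0.25, σ_el = 0.80).  The floor
  encodes the clinical definition — an MR diagnosis requires a palpable
  ridge;
* a **frontal wedge** (TG only): lateral compression of the anterior third
  (0.18 ± 0.025), producing the triangular forehead and acute IFA;
* **hypotelorism offsets** on the medial orbital landmarks (TG 1.55 mm per
  side, MR 0.75, C 0), with orbital height/width factors 0.866 / 0.920 /
  0.886;
* isotropic **growth** `(age/220 d)^0.1`, so ICV rises monotonically with
  age; TG gets a thinner vault (3.2 vs 4.5 mm) and slightly wider axes,
  yielding the larger ICV at matched age reported clinically.

Ages are truncated normals matching the study design — TG 219.3 ± 81.4 d,
MR 379.25 ± 224.7 d, C 218.7 ± 107.8 d on [30, 900] — with girl fractions
0.30 / 0.407 / 0.511 and default sizes 90 / 27 / 90.  Supra-orbital notch
placement carries substantial between-subject variability (azimuth
SD 0.12 rad, clamped away from the midline so the notch can never approach
the apex and degenerate the angle); this is what makes IFA an honest but
imperfect discriminator, as the diagnostic comparison requires.  Cranial
landmarks are evaluated through the same deformation chain and snapped to
the noisy vault; the intracranial surface is the noise-free vault offset
inward by the vault thickness.  Everything is deterministic given the
seed, and the drawn ground-truth parameters are stored per subject for
recovery tests (measured IFA and CURV are monotone in the wedge and crease
knobs with |Spearman ρ| > 0.95 across 25 noise-suppressed severity
levels).

**What the generator does and does not emulate.**  It reproduces the
*contrast structure* of the three phenotypes — CURV greatest in TG and
lowest in controls, DIST the reverse, IFA most obtuse in controls and most
acute in TG, MR overlapping controls everywhere except the crease, MR's
wide age distribution driving its confusability in unsupervised
clustering — but not absolute clinical magnitudes.  Synthetic IFA runs
roughly 20° more obtuse than clinical values because the parametric vault
has no recessed supraorbital bar, and CURV magnitudes sit at the physical
scale of an 80 mm skull (~0.02–0.04 mm⁻¹), not at the several-mm⁻¹ scale
sometimes printed clinically.  One emergent artefact of the age structure
deserves note: because curvature scales as 1/size and the MR group is
older, MR-vs-control profile differences acquire a small global offset
beyond the crease region, so their significant set can extend past the
glabellar window at large n.  Consequently, passing tests establish that
the *pipeline* detects and classifies the encoded morphology correctly —
they are not a clinical validation on real skulls, which additionally vary
in suture anatomy, vault thickness maps and segmentation noise.

## Problem sizes and reproducibility

The reference study runs 30 TG / 27 MR / 30 C at seed 0 — large enough for
every stage (bootstrap bands, permutation tests, the KNN split, Ward
clustering) to behave as designed while keeping a full end-to-end run in
the low minutes on one CPU; the statistical calibration uses 500 null
replicates at 199 permutations.  All randomness flows through explicit
seeds; rerunning any script with the same configuration reproduces its
numbers bit-for-bit.
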
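# Methods

This note documents the models behind `hepavol`: what the synthetic phantoms
emulate, how the simulated automated segmentation works, how the volumetry
and classification rules are operationalized on voxel grids, and which
statistical conventions the agreement toolkit follows. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Label model

A case is a single 3D integer label grid with physical voxel spacing (mm).
Every voxel carries at most one label. The liver parenchyma is stored as the
resection partition `REMNANT` / `RESECT`; lesions and vessels carve their own
voxels out of it, so the *blood-filled* liver region is the union
parenchyma ∪ lesion ∪ intrahepatic vessels, and the *blood-free* region drops
the vessel voxels. The inferior vena cava (`IVC`) is a landmark outside the
liver and is never counted in any liver volume.

Intrahepatic vs extrahepatic vessel voxels are decided as follows: the five
hepatic veins and the right/left portal veins are intrahepatic by the
annotation protocol they emulate; the main portal vein (`MPV`) counts only
where it falls inside the hole-filled liver region. The phantom constructs
the MPV to stop at the liver surface, so on phantoms the rule is exact. For
external volumes, an MPV segment whose tunnel opens to the liver surface is
treated as extrahepatic — a known approximation of the hole-filling
heuristic.

## Phantom generator

The generator produces the *study conditions*, not patient anatomy:

- **Liver**: an ellipsoid (default semi-axes 50 × 38 × 30 mm on a 128³ grid
  at 1 mm isotropic spacing) deformed by a smooth Gaussian random field
  (amplitude 0.12 on the implicit function). Liver condition acts
  qualitatively: *fatty* scales the axes by 1.06; *cirrhosis* by 0.86 with
  doubled surface irregularity. No validated shape model exists for diseased
  livers, so these effects are placeholders and must not be read as anatomy.
- **Vessels**: capsule-swept jittered polylines. Each named vessel has a
  trunk, two primary branches, and short secondary stubs (annotation depth
  "to the second ramification"); radii taper by 0.65 per generation and are
  floored at 1 mm radius (the 2 mm diameter annotation floor — a trunk radius
  below the floor is a hard error). Hepatic veins fan out from the IVC
  confluence; portal branches from the porta hepatis; the MPV approaches the
  porta from outside the liver; the IVC is a straight vertical tube behind
  the liver. Growth is steered: points keep a depth margin inside the liver
  (EDT ≥ 1.45 r + 0.8 mm) and a clearance from previously built trees
  (KD-tree of axis samples, ≥ 1.3 (r₁ + r₂) + 0.6 mm), which guarantees that
  tubes of different labels never intersect — necessary because composition
  is single-label-per-voxel and an overwrite would break ground-truth
  continuity. Infeasible roots are retried with jitter toward (or away from)
  the liver centroid, shrinking the tube radius from the fourth attempt.
- **Blood-pool calibration**: tube radii are pre-scaled analytically from
  the planned tree volume (fraction ∝ r²L/V) and then rescaled at most four
  times after rasterization (scale clamped to [0.7, 1.3]) until labeled
  vessels inside the liver occupy the target fraction of the liver volume —
  default 9%, the conventional figure for the hepatic blood pool. Landing
  outside ±25% (relative) of the target is an error. Across 144 stress
  phantoms the achieved fraction stayed within [0.082, 0.091].
- **Resection**: an oblique plane (x axis ± a ~6° random tilt) whose offset
  is the exact quantile of liver-voxel projections, so the resected
  parenchyma fraction matches the preset: left 0.33, right 0.62,
  extended-right 0.75. The plane is stored with the phantom and reused by
  the volumetry, making side attribution of lesion/vessel voxels exact.
- **Lesion**: a sphere (radius 8–16 mm by default) placed on the resected
  side with a depth margin, mirroring that resection candidates carry the
  tumor in the resected territory.
- **Cohorts**: conditions and resection types are allocated by largest
  remainder from configurable mixes; the defaults (27 healthy / 3 fatty /
  2 cirrhotic and 10 left / 21 right / 1 extended-right per 32 patients)
  reproduce the composition of a typical major-hepatectomy candidate cohort.
  Per-patient seeds derive from the master seed via named CRC-based
  substreams, so any patient can be regenerated in isolation and identical
  (config, seed) pairs give bit-identical volumes.

## Simulated automated segmentation

A trained segmentation model is out of scope; its error structure is
simulated. Each structure's boundary is displaced by adding a smooth
Gaussian random field (σ = 6 voxels; 9.6 for the parenchyma, whose errors
are larger-scale) to its signed Euclidean distance function and
re-thresholding at zero. Because every voxel flips state at most once as the
field amplitude grows, the group Dice score is non-increasing in the
amplitude, and a bisection finds the amplitude whose group DSC lands within
±0.05 (inner tolerance 0.015) of the requested target. Defaults target
DSC 0.66 for hepatic veins, 0.67 for portal veins — the performance range
reported for 3D U-Net vessel models — and 0.97 for the whole liver, where
automated segmentation is near ceiling. A target of `None` applies a fixed
amplitude instead (useful for monotonicity experiments). Whole primary
branches can additionally be dropped with a configured probability
(ownership of each vessel voxel is decided by its nearest centerline, so a
dropped branch takes its sub-branches with it); dropout combined with a
DSC target of 1.0, or a target below what dropout alone leaves, is an
error rather than a silent miss.

The liver-group bisection measures DSC exactly as it is later reported
(vessel voxels carved out of the parenchyma mask), so the achieved scores in
a pipeline run match the targets without post-hoc correction. What this
simulator does **not** reproduce: CT intensities, anatomically structured
failure modes (contrast timing, tumor infiltration), inter-reader
variability, or correlated errors between structures. Passing tests
demonstrate the pipeline's arithmetic and statistics, not clinical
segmentation performance.

## Volumetry conventions

- Lesion voxels count inside TLV in both settings and inside FLR when on the
  remnant side; `V_Lesion` is subtracted only in the FLR% denominator,
  exactly as the defining equations require. One consequence, covered by a
  test: a lesion attributed to the remnant side can push FLR% above 100 in
  pathological constructions.
- Side attribution of lesion/vessel voxels uses the resection plane when
  available, otherwise the side of the nearest parenchyma voxel (EDT). The
  identity FLR_filled − FLR_free = (vessel volume on the remnant side) is
  voxel-exact under either rule.
- Candidacy uses a strict inequality ("larger than" 20/30/40%); FLR% exactly
  at the threshold is not a candidate.
- Volumes are mL = voxel count × voxel volume (mm³) / 1000, full precision
  internally, 2 decimals in serialized outputs.

## Classification criterion

"Accurately and continuously annotated" is operationalized as: resample the
ground-truth centerline at min(spacing)/2; a sample is *covered* when it lies
within the predicted mask dilated by a tolerance (default one voxel — the
criterion was designed for visual application, and one voxel is its natural
digital slack); the vessel part passes when the **longest contiguous covered
run** reaches ≥ 3/4 of the trunk length, or ≥ 1/2 of each primary branch's
length. Thresholds are inclusive; a branch row passes only if *every*
primary branch passes (one figure per vessel per case is reported, and the
all-branches reading is the conservative one). Coverage is evaluated via the
Euclidean distance transform of the mask complement, cropped around the
centerline (exact for all distances below the crop pad). Enlarging a
prediction can never flip a verdict from accurate to inaccurate; this
monotonicity is property-tested.

`extract_centerline` (skeletonize → prune spurs ≤ 4 voxels → require a
simple path) exists as an independent cross-check of phantom ground truth,
not as part of the criterion.

## Statistics

- **Bland–Altman**: bias = mean difference; 95% limits of agreement =
  bias ± 1.96 × sample SD (n−1); bias significance by two-sided one-sample
  t-test. A zero-variance difference set reports p = 1 rather than failing.
- **McNemar**: exact binomial, p = min(1, 2·P(X ≤ min(b, c))) with
  X ~ Binomial(b+c, ½); p = 1 when no discordant pairs (the all-concordant
  candidacy table therefore prints p = 1 > 0.99). Cross-checked against
  statsmodels' exact McNemar in the tests.
- **Mann–Whitney U**: for pooled n ≤ 20, exact enumeration of all group
  assignments with midrank ties (two-sided by distance of U from its null
  mean); otherwise the normal approximation with tie and continuity
  correction. Type-I error is simulation-tested to lie in [0.03, 0.07] at
  α = 0.05. Manual-vs-automated comparisons are unpaired by the design being
  emulated, even though a paired test would be more powerful.
- **Kruskal–Wallis** with tie correction for condition-subgroup comparisons
  (the conventional omnibus choice when the source analysis names none);
  all-identical input returns H = 0, p = 1.
- **Wald 95% CIs** for accuracy proportions, clipped to [0, 100]; chosen
  because published accuracy tables of this kind back-calculate to Wald
  intervals. The degenerate zero-width interval at k = 0 or k = n is the
  known Wald pathology and is kept deliberately.
- Empty-mask conventions: DSC = VS = 1 for two empty masks (perfect
  agreement on absence); VS = 0 when exactly one is empty.

## Problem sizes and determinism

Defaults are desk-scale by design: 128³ grids at 1 mm (the full 32-patient
pipeline runs in ~2–3 minutes on one CPU); the test suite uses 96³ grids
with a proportionally smaller liver. All randomness flows from one master
seed through named substreams (`phantom/patient-i`, `perturb/patient-i`,
per-vessel tree streams), and end-to-end runs are byte-deterministic given
(config, seed) — serialized reports differ only in their timestamp field.

## Known limitations

- Phantom livers are deformed ellipsoids; vessel trees are geometrically
  plausible but not hemodynamically or topologically faithful (no Couinaud
  segments, no accessory right hepatic vein, no vessel-lesion interaction).
- Condition effects (fatty/cirrhotic) are qualitative placeholders.
- The hole-filling rule for intrahepatic MPV voxels under-counts segments
  whose tunnel reaches the liver surface in externally supplied volumes.
- The perturbation model's noise is spatially smooth and structure-
  independent; real automated-segmentation errors are not.
- Classification accuracy measured on phantoms depends on the perturbation
  model and must not be read as a claim about any real segmentation model.
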
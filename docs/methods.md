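# Methods

This note documents the models and numerical choices behind `psiplace`:
what is computed, what the synthetic data emulate, and where the design
was genuinely open.

## Geometric conventions

All coordinates are millimetres in a right-handed frame (the clinical CT
convention). Rigid transforms are proper motions $(R, t)$, $\det R = +1$,
acting on column points as $p' = Rp + t$; `compose(T2, T1)` applies `T1`
first. Orthonormality is enforced at construction to $10^{-9}$ and
re-orthonormalized (SVD) after every least-squares solve, so long
composition chains stay valid. Meshes are `trimesh.Trimesh` objects;
loading merges duplicate vertices and drops faces below $10^{-9}$ mm²
because the closest-point and plane-section queries assume sane topology.

## Registration

**Paired-point.** The closed-form SVD (Horn/Kabsch) solution of
$\min \sum_i \lVert R m_i + t - f_i \rVert^2$, with the determinant
correction that excludes reflections. Points are matched by label, at
least three non-collinear pairs are required (collinearity is detected by
the second singular value of the centered point matrix). The RMS residual
is the fiducial registration error.

**ICP.** Alternates exact closest-point-on-triangle correspondence (a
vectorized point-to-triangle projection over candidate faces — not a
nearest-vertex approximation) with the paired-point update. Because each
update minimizes the distance to the previous correspondences and the new
correspondences can only be closer, the point-to-surface RMS is
non-increasing; the per-iteration sequence is recorded and tested.
Defaults: 50 iterations maximum, stop when the RMS change drops below
$10^{-6}$ mm, no outlier trimming — the intended operating point is
low-noise (sub-0.1 mm surface residuals), where trimming has nothing to
reject. "Registration error" here means the RMS point-to-surface
residual; the maximum residual is reported alongside.

Point-to-point ICP converges slowly along tangential sliding modes of
smooth surfaces. Registration surface points are therefore taken *spread*
across the bone (farthest-point subsampling of an area-weighted candidate
pool), which both mirrors how a navigation protocol records surface
points and conditions the pose well. With clustered random samples the
residual can stall near 0.07 mm from a 2° / 1 mm perturbed start; with
spread samples it passes below 0.05 mm within the default iteration
budget.

**planToReal.** The placed guide's pose change is estimated from its four
pinhole fiducials by the same paired-point solver. Exactly four labeled
pinholes are required (the guide protocol), and both sets must already be
in the bone frame — tracker-frame measurements are mapped through the
estimated bone registration first; passing tracker-frame points raises an
error rather than silently mixing frames.

## Osteotomy sections and the MOD

The cut is modeled as a plane; the bone stays fixed and the *plane* is
moved by planToReal (origin $Ro + t$, normal $R\hat n$), then
re-intersected. Plane–mesh intersection collects all triangle-edge
crossing segments (via `trimesh`), chains them into polylines, and
resamples each at uniform arc length (default 0.1 mm), making the point
density independent of mesh resolution. All connected components are kept
by default; an option restricts to the component nearest a given point
(e.g. the guide footprint) for bones where the plane crosses disconnected
structures.

The deviation is the *directed* closest-point distance from every planned
section point to the achieved section's point cloud; the maximum is the
MOD. Distances are unsigned 3-D Euclidean (whether to measure within the
plane instead was open; 3-D was chosen as the stricter, simpler metric).
The direction planned→achieved matters and the asymmetry is covered by a
test. With 0.1 mm resampling the discretization error is two orders of
magnitude below typical reported deviations (0.3–50 mm); halving the
spacing changes the MOD by less than the spacing on the synthetic
phantom. A moved plane that misses the bone entirely raises an explicit
off-bone error; the pipeline records such trials separately and never
clamps them, because gross misplacements are precisely the tail the
statistic must not mask.

## Synthetic phantom and placement models

No phantom geometry is deposited with placement studies of this kind, and
the assessment pipeline is shape-agnostic, so the phantom is a parametric
stand-in rather than a pelvis reconstruction. It is an ellipsoidal shell
sector (~180 mm scale, ~10k triangles, deterministic per seed) with the
two features the regional analysis depends on:

* a broad low-curvature **crest band (C)** along the top, with a seeded
  random bump texture whose amplitude scales with
  $1-\text{crest\_homogeneity}$ (default 0.5) and ramps up along the band
  — so the low end of the crest is smooth/featureless and the high end is
  "featured";
* a narrow, deep **notch (S)** (depth 3.5% of scale, σ ≈ 3% of the
  parameter range) giving the high-curvature characteristic region.

With `crest_homogeneity = 1` the maximum angle defect in the band is
~0.0006 rad vs ~0.23 rad at the notch — a 400× contrast, verified by
test. Six paired scenarios place one guide per region: C guides vary in
footprint (22–40 mm) and position (two small guides on the smooth crest,
two large ones on the featured crest, mirroring the size/location
contrast placement studies examine); S guides cluster at the notch with
14–18 mm footprints. Pinholes are the four corners of a footprint
rectangle projected to the surface and offset 2.5 mm outward (the guide
body). Plane origins lie on the surface with tangent normals, so every
plane intersects the phantom by construction.

**Placement error.** Each trial draws a rotation of magnitude
$|N(0,\sigma_{rot})|$ about a random axis through the footprint centroid
plus an isotropic $N(0, \sigma_{trans})$ translation. Defaults: freehand
2° / 1.5 mm, smartphone 1° / 0.5 mm, HoloLens 1.1° / 0.55 mm. A
soft-tissue ("silicone") layer adds 0.8 mm to the translation scale. The
freehand model additionally slips with probability 0.15 — but only in the
C region, along the crest tangent (the direction in which a homogeneous
surface provides no registration cue) — by
$8\,\text{mm} \cdot (1 + \mathrm{Exp}(1))$, producing the heavy tail of
gross misplacements. These parameters are loose calibrations chosen once
so that simulated medians land in the plausible 1–3 mm range with rare
multi-centimetre freehand outliers; they are configuration values, not
fitted quantities, and nothing downstream asserts their specific output
levels beyond ordering.

**Measurement.** Pinholes are read with isotropic Gaussian pointer noise
(default σ = 0.2 mm) in the tracker frame and mapped back through the
estimated registration.

What the simulator does *not* emulate: case-dependent error magnitudes
(the per-case geometry varies but the noise law is shared, so per-case
rank tests are near-null by construction), anisotropic tissue thickness,
user learning effects, and any human timing behavior. Passing tests
therefore validate the geometry/statistics pipeline and the qualitative
method/phantom contrasts — not any quantitative claim about real
placement accuracy.

## Experiment pipeline

Default design: 4 users × 6 cases × 2 regions × 3 methods × 2 phantom
variants = 288 trials. The bone registration is performed once per
phantom variant from noiseless landmarks + spread surface points and
reused for all its trials, matching the physical protocol of registering
once at the start. Per-trial randomness comes from independent
`SeedSequence` streams keyed by (master seed, case, region, method,
phantom, user); each trial's integer seed is stored in the output table,
and re-running a trial from its stored seed reproduces its MOD exactly.
Off-bone trials are tabulated separately and excluded from order
statistics and rank tests.

Planned sections are computed once per case and cached; a full experiment
runs in a few seconds on one CPU, and the replicate-ordering test runs 20
complete experiments.

## Statistics

Quantiles use linear interpolation between order statistics (numpy
default); the convention cannot be recovered from typical published
tables, so one was fixed and documented. Kruskal–Wallis delegates to
`scipy.stats.kruskal` (tie-corrected H, chi-square reference with k−1
df); all-identical data raise an explicit error since the tie correction
degenerates. Dunn's post-hoc test is implemented directly (mean-rank z
with tie-corrected pooled variance, two-sided normal p); it is verified
against an exact-rational-arithmetic fixture and against the asymptotic
Mann–Whitney test, to which it reduces for two groups. The default
multiplicity adjustment is *none* (published pairwise p-values of this
kind are typically reported unadjusted); Bonferroni and Holm are
available. The pooled "Total" column is a simple pooling of S and C
trials; its min/max are the region-wise min/max, while the pooled median
may legitimately fall outside the two region medians (a test documents
this).

## Known limitations

* The phantom is a smooth parametric shell; real iliac geometry has
  ridges and foramina that change both ICP conditioning and section
  shapes.
* MOD is a point-cloud statistic; it does not measure cut-surface area or
  resection-margin status relative to a tumor model.
* The placement models are stipulated, not fitted to recorded placements;
  only their ordering (freehand worst, tissue harder) is treated as
  meaningful.
* ICP is untrimmed and point-to-point; heavy measurement outliers or
  large initial misalignments are out of scope.
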
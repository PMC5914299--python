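# Methods

`nervemosaic` reconstructs wide-field mosaics of the corneal subbasal
nerve plexus (SBP) from overlapping in vivo confocal microscopy (IVCM)
frames, traces the nerve fibers, computes nerve fiber length densities
(CNFL), and quantifies the sampling bias of single-field CNFL estimation.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic phantom does and does not establish.

## Mosaicking model

A confocal frame is scanned row by row, so lateral eye motion during the
~1/8 s frame time displaces individual pixel rows rather than the frame as
a whole. The registration unit is therefore not the frame but one of 12
equal horizontal stripes (32 rows each for the standard 384×384 frame):
narrow enough to be internally near-rigid, tall enough to correlate
reliably.

For every unordered frame pair (all N(N−1)/2 of them — no acquisition
pattern is assumed), stripes of one frame are matched against windows of
the other, each validated match yielding one linear constraint
`p_(j,n) − p_(i,m) = u` on the unknown mosaic positions of the stripes.
The pooled sparse system is solved by regularized least squares with

- a discrete-curvature penalty on the 12 stripe positions *within* each
  frame (weight λ, default 0.1), applied per frame and never across
  frames — the smoothness partitioning that makes independent frame
  acquisition well-posed;
- a weak prior toward the nominal 32-px vertical stripe spacing
  (weight 0.05) that fixes the within-frame layout when a frame has no
  matches (a single unmatched frame resolves to a straight vertical
  chain at 32-px spacing);
- one stripe anchored at the origin per connected component (gauge).

λ trades distortion-tracking fidelity against noise: values near 1
visibly flatten a 4-px motion curve (verified against phantoms with
known displacement), while 0.03–0.1 perform equivalently; 0.1 is the
default.

A cubic interpolating spline through each frame's 12 solved anchors
(parameterized by stripe-center row, fitted separately per coordinate,
linear beyond the end anchors) yields a mosaic position for all 384 rows.
Rows are forward-splatted bilinearly at their curve positions and the
mosaic is the weighted average of all warped frames, with a separable
raised-cosine window (full weight over the central 50% of the frame)
down-weighting frame borders. Frames not connected by validated matches
form separate components and produce separate mosaics, ordered by
coverage.

### Translation measurement

The coarse inter-frame offset comes from whole-frame phase correlation
with wrap disambiguation by masked spatial correlation
(`skimage.registration.phase_cross_correlation`). The per-stripe residual
is then measured by an exhaustive local normalized-cross-correlation
search (±6 px, parabolic sub-pixel fit) on high-pass content. FFT phase
correlation is deliberately not used at the stripe level: a 32-row band's
circular wrap creates an edge artifact at zero lag that biases the phase
peak toward the window placement (≈1.7 px systematic error on a 2 px
residual in controlled experiments), whereas the direct NCC search has no
wrap and resolves ≈0.07 px median error on phantoms. `phase_correlate`
remains available and is what the pair-level stage uses.

### Robustness

Three guards keep rare spurious correlations from corrupting the global
geometry, each measurable on phantoms where a single false pair link can
displace a whole raster row by hundreds of pixels:

- the coarse offset of a pair must achieve a high-pass overlap NCC ≥ 0.5
  (low-frequency texture correlates between unrelated frames; structure
  does not);
- a pair contributes graph edges only with ≥ 3 validated stripe matches;
- the least-squares solve trims matches by residual in passes (8 → 3 →
  1 px) and re-solves, recomputing connected components after trimming.

A second registration pass then re-registers every pair whose *solved*
geometry predicts an overlap. This recovers small-overlap diagonal
neighbors whose coarse correlation failed and roughly doubles the number
of constraints.

### Observability limit of motion correction

Pairwise registration cannot observe a smooth displacement field applied
to the whole mosaic: adding any smooth warp `F(y)` to every frame's curve
leaves every pairwise measurement unchanged. The practical consequence is
an error floor equal to the local average of the overlapping frames' true
per-row displacements, ≈ σ_d/√K for K-fold coverage. Denser overlap is
the only remedy; the motion-correction validation therefore runs at 60%
overlap (K ≈ 5), consistent with the heavily oversampled clinical
acquisition this pipeline targets (hundreds of raw frames per mosaic).
`refine_motion_curves` implements a fine-band (8-row) bundle refinement
with a per-frame rigidity datum; it sits at the same observability floor
and is provided as an option rather than a default stage.

## Nerve tracing

Enhancement is the per-pixel maximum even-symmetric response of a
log-Gabor bank (8 orientations × wavelengths 6/12/18 px ≈ 2–6× the
expected 3-px fiber width at the native 400/384 μm/px scale; radial
bandwidth ratio 0.65). The response is hysteresis-thresholded at
fractions (low 0.35, high 0.55) of a robust response maximum (99.5th
percentile of in-coverage response), which makes the cut scale- and
illumination-independent; the binary map is skeletonized and split into
branchless centerline polylines at junctions (redundant diagonal links
pruned first), and segments shorter than 12 px are dropped.

Candidates are classified nerve/"other" by an RBF-kernel SVM
(standardized features: length, intensity mean/SD, local contrast, mean
curvature, width from the distance transform, response mean/SD). The
training corpus is generated programmatically from phantom scenes whose
ground-truth centerlines label the candidates (a candidate is a nerve if
≥ 80% of its points lie within 3 px of a true centerline); scenes are
rendered with elevated noise so the "other" class has genuine members.
Large mosaics are traced in overlapping tiles, a segment being kept by
the tile that owns its midpoint; tiled and untiled results agree within
2% on phantoms.

mCNFL divides total traced centerline length (mm) by the effective
(coverage minus exclusion) mosaic area (mm²). wCNFL restricts both to the
800 μm-diameter disc around a supplied whorl center; only covered,
non-excluded disc pixels count toward the area, so partial coverage is
handled explicitly. Manual (.ndf) and automatic tracings flow through the
same length/area code paths.

## Sampling-bias analysis

Non-overlapping 400×400 μm fields are selected greedily in acquisition
order at the actual solved frame locations (accept iff fully inside
coverage and overlapping no accepted field; deterministic; up to 20).
Per-field CNFL is computed two ways: the mosaic tracing clipped to the
field (depth-corrected scenario) or an independent automatic tracing of
the originating raw frame (raw scenario); both divide by the fixed
0.16 mm² field area. For each sample size k the relative error of the
mean CNFL versus the mosaic reference,
`100·(mean CNFL − mCNFL)/mCNFL` (positive = overestimate), is evaluated
over every combination of k fields — exhaustively whenever C(n, k) ≤
200,000, which covers every n ≤ 20 exactly; beyond that, seeded uniform
combination sampling. Combination SDs are population SDs over the
enumerated set.

## Agreement statistics

Pearson correlation (two-tailed p from the t distribution, n−2 df) and
classical Bland–Altman agreement: differences x − y, SD with the n−1
denominator, and 95% limits of agreement at mean ± 1.96·SD (a fixed
normal quantile, not a t quantile). The LOA half-width is therefore
exactly 1.96 × SD — for an SD of 1.38 mm/mm², ±2.71 mm/mm².

## Synthetic phantom

The generator renders a wide-field scene at the native frame scale:
bright fibers entering from the border and spiralling toward an
infero-central whorl with sinusoidal tortuosity (default 14 nerves,
3 μm width, 12 μm tortuosity), on a low-contrast two-scale random-blob
background standing in for the basal epithelial cell mosaic — the texture
that anchors registration in nerve-free regions of real images. The
scene is raster-scanned into 384×384 frames (default 5×5 grid, 40%
overlap, ±4 px position jitter emulating manual scanning) with three
acquisition artifacts:

- per-row horizontal scan displacement: a random walk low-pass filtered
  over 30 rows (spline-representable at the 32-row stripe spacing),
  zero-mean, rescaled to a stated peak amplitude (default 2 px);
- additive Gaussian noise (default SD 0.02 of the dynamic range).

Two acquisitions are rendered at the same positions. `acquire_frames`
gives the *depth-corrected* sequence that feeds mosaicking: adaptive
focus found the plexus everywhere, matching the clinical workflow in
which incorrectly focused images are excluded before mosaicking.
`acquire_raw_frames` gives the *non-depth-corrected* single images used
by the raw sampling scenario: a stated fraction of positions (default
20%) miss the thin plexus and show the epithelial layer instead — cell
texture sharp, nerves reduced to a blurred remnant at 25% gain — which
is what a confocal section at the wrong depth actually looks like
(sharp wrong-layer content, not optical blur).

Ground truth records the exact centerlines, frame positions, per-row
displacements and defocus flags; everything is deterministic given the
seed.

What the phantom does *not* emulate: the instrument's point-spread
function and speckle statistics, dendritic cells, depth stacks as
explicit z-series (focus variation across frames is the modeled
consequence), curvature-induced intensity falloff, and blinks/saccades
larger than the smooth per-row model. Passing phantom tests therefore
demonstrates the correctness of the algorithms under the stated
acquisition model, not clinical-grade performance on patient images.

## Validation problem sizes

The test suite and the acceptance script run: registration on a 5×5
raster at 40% overlap (25 frames, 300 candidate pairs); motion
correction on a 5×5 raster at 60% overlap with 4 px peak displacement;
mosaic splitting on two disjoint 2×2 clusters; tracing on a noise-free
5×5 mosaic (~1.8 mm²); and the bias analysis on a 7×7 raster (49 frames)
with 30% out-of-focus frames, yielding ≥ 12 non-overlapping fields.
These sizes exercise every stage end-to-end while keeping a full run in
minutes on one CPU.

## Known limitations

- Motion correction accuracy is bounded by the pairwise observability
  floor discussed above; reported row-position RMS on phantoms is
  ~0.7–1.3 px at 4 px peak distortion depending on the realization.
- The SVM is a structural stand-in trained on phantom data; for clinical
  images it should be retrained on expert-labeled candidates (the model
  is an explicit input everywhere).
- Vertical (row-pacing) scan distortion is modeled by the solver but not
  generated by the phantom, so it is untested against truth.
- The whorl center is an expert-supplied input; no automatic detection.
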
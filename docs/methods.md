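# Methods

This note records the models, conventions and numerical choices behind
`otoshape`, and what its synthetic data can and cannot show about real
otolith photographs.

## Shape signature

The unit of analysis is a closed outline. We reduce it to a one-dimensional
periodic signal: 512 points at equal arc-length spacing along the polygon
(linear interpolation between source vertices), each point's distance to the
polygon's **area** centroid (shoelace moments — robust to uneven vertex
density, unlike the vertex average), divided by the mean distance and
circularly rotated so index 0 is the farthest point from the centroid.

Choices worth stating:

- **Mean-radius normalization** (signature mean = 1) rather than max-radius:
  dividing by the maximum would pin index 0 at exactly 1 and erase rostrum-
  size information; the mean preserves relative feature amplitude while
  removing absolute scale.
- **Start point** at the farthest point from the centroid makes signatures
  comparable across specimens; exact ties are broken toward the smallest
  polar angle from the positive x-axis (deterministic, orientation-stable)
  with a logged warning. On a circle every point ties; the convention still
  returns a well-defined (arbitrary) start.
- **Orientation**: counterclockwise traversal is canonical; right otoliths
  are mirrored about the vertical axis and re-ordered. All analyses assume
  the left-otolith pose (sulcus up, rostrum right).
- **Discretization limits.** The signature is exactly invariant to
  translation and uniform scaling (tested at 1e-12). Invariance to the
  starting vertex of the input polygon and to mirroring holds exactly only
  in the continuum: re-resampling from a shifted start moves the sample
  phase, a second-order-in-spacing effect of order 2e-5 on a typical outline
  at 512 points. Tests bound it at 1e-4.
- Mask extraction traces the largest foreground component with marching
  squares at the half-level, in pixel-center coordinates, holes ignored.
  The render → extract → signature round trip reproduces a source signature
  to well under 1% mean absolute deviation at 256 px/unit.

## Wavelet features

The à trous (stationary, undecimated) transform with the B3-spline mask
(1, 4, 6, 4, 1)/16: at level j the mask is dilated by inserting 2^(j−1) − 1
zeros between taps, convolved circularly (the signature is periodic, so
wrap-around is the only artifact-free boundary), and the detail is the
difference of successive smoothings. Nine levels from a 512-sample signal
(2⁹ = 512), with the final smooth kept separately from the nine details.
Reconstruction smooth + Σ details is a telescoping identity, exact to float
precision. Detail scale 4 (structure of roughly 2⁴ samples ≈ 3% of the
perimeter — rostrum, antirostrum, notch width) is the default feature
vector; the scale is a parameter, not a constant.

Group summaries (mean ± SD per contour position) use sample (n−1) standard
deviations; singleton groups report zero SD.

## Morphospace and allometry

PCA is computed on the variance–covariance matrix of the mean-centered
feature matrix (no per-column scaling: wavelet coefficients share units and
their relative amplitudes are signal). Eigenvector signs follow a
deterministic convention (largest-magnitude element positive). Retention
uses the broken-stick rule over the positive (effective-rank) eigenvalues,
taking the **leading consecutive run** above expectation — stopping at the
first failure — rather than every component anywhere above it (switchable).
If fewer than 2 components are retained the pipeline stops with guidance
rather than silently proceeding.

Size correction: Pearson correlations of each retained score with otolith
length serve as a screen (no multiple-testing correction is applied to the
screen; the output says so). Residualization subtracts the pooled
within-group slope, y′ = y − b(x − x̄_grand), rather than taking full ANCOVA
residuals: per-group residuals would also strip the group intercepts, which
are exactly the signal the downstream classifier and clustering need. By
default all retained components are adjusted; a switch restricts adjustment
to components whose size correlation is significant at a chosen alpha. The
within-group correlation of adjusted scores with size is exactly zero when
the size–shape relation is exactly linear and shared; with finite noisy
samples it fluctuates at the 1/√n scale like any sample correlation.

## PERMANOVA

Implemented from the partition SS_total = (1/N) Σ_{i<j} d²ᵢⱼ,
SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ, with
pseudo-F = (SS_among/(a−1)) / (SS_within/(N−a)) on Manhattan distances.
p-values come from unrestricted random label permutations with the observed
statistic counted in the null set (p ≥ 1/(n_perm + 1)); ties count as
exceedances (conservative). Small designs (N ≤ ~10) can be tested exactly
by enumerating all distinct label arrangements. Pairwise tests re-permute
within each pair's submatrix and are Bonferroni-corrected
(p_adj = min(1, p × number of pairs)). Zero within-group distance yields
F = +∞ with the p-value still defined by permutation. The permutation
engine is vectorized over label shuffles; 999 permutations on N = 16 run in
about a millisecond, and the null rejection rate at α = 0.05 is calibrated
(checked against the binomial interval over 500 null simulations).

## Classification

A single-hidden-layer perceptron (logistic hidden activations, one output
per class, highest-output decision, ties toward the first class in label
order) trained with L-BFGS, deterministic given a seed. Under leave-one-out
cross-validation, for every held-out case the remaining N−1 observations
are (1) centered and scaled on their own statistics (constant columns are
centered only, with a warning), (2) SMOTE-balanced up to the majority count
— synthetic rows x_i + u(x_nn − x_i) with x_nn among the k = 5 nearest
same-class neighbors and u ~ U[0,1] — and (3) used to tune the hidden-layer
width by inner stratified k-fold accuracy before the final fit. SMOTE runs
strictly inside training folds: balancing before the split would plant
near-copies of the held-out case in the training set and inflate accuracy.
The full LOOCV loop repeats with fresh seeds (both SMOTE and weight
initialization vary per repeat); the reported matrix is the per-repeat mean
with per-repeat metrics retained, since means of counts need not be
integers.

Metrics on the prediction × reference matrix: accuracy = trace/N; Cohen's
kappa with chance agreement from the row/column margin products (undefined
and reported as NaN when the margins are degenerate); per-class accuracy =
diagonal over reference-column total. The packaged 11-river American shad
matrix (N = 1141) is a worked example: accuracy 0.9089, kappa 0.8945,
per-class accuracy from 82.13% to 100%.

Component relevance uses permutation importance (mean in-sample accuracy
drop over label-preserving column shuffles, averaged over a small model
ensemble) — descriptive, not inferential.

## Morphotypes

Hierarchical clustering in the classic `ward.D` form: the Lance–Williams
ward update applied to the **unsquared** Euclidean distances
(d(ij,k) = [(nᵢ+nₖ)d(i,k) + (nⱼ+nₖ)d(j,k) − nₖ d(i,j)]/(nᵢ+nⱼ+nₖ)). This is
deliberately not the ward.D2 variant (which squares distances first and is
what `scipy.cluster.hierarchy.linkage(..., 'ward')` computes); the two give
different trees. Exact ties merge the lexicographically smallest pair of
cluster indices. Cutting undoes the last k−1 merges; clusters are labeled
1…k by first appearance. Clustering operates on the size-adjusted retained
PC scores (same matrix as classification; switchable to raw wavelet
features). k is an explicit parameter — 5 is a sensible default for this
kind of data but silhouette widths for k = 2…10 are emitted to support the
choice. Testing cluster-derived labels with PERMANOVA on the same matrix is
circular and anticonservative; the function warns and tags its result
accordingly.

## Synthetic data

Shapes are polar functions around an ellipse: r(θ) = r_ellipse(θ) · m(θ)
with m(θ) = 1 plus von-Mises-shaped bumps — rostrum at the signed elevation
angle (positive = upper rostrum, negative = lower), a narrow negative notch
bump and an antirostrum bump at fixed offsets above the rostrum, a broad
posterior bump at θ = π — plus random low-order harmonics (k = 2…8, SD
`irregularity_sd`/k). A single-valued positive radius makes every shape
star-shaped and therefore simple; a draw where m(θ) ≤ 0 anywhere is
rejected and redrawn (bounded at 100 retries). Populations add Gaussian
per-individual parameter spread, an allometric per-mm parameter shift, and
truncated-normal otolith lengths (axes scale isometrically with length);
metapopulations fan per-population seeds out of one master seed, so
generation is exactly reproducible.

Defaults emulate the eleven-river American shad survey design: sample
sizes 18–278 (total 1141), otolith lengths ~3.9–4.3 mm with the per-river
means and SDs of that survey, a north-to-south gradient from upper- to
lower-rostrum shapes, a deeper notch in the northernmost river, and a mild
allometric slope of rostrum prominence on otolith length.

Two deliberate design points:

- **Elevation is mostly a rotation.** Because the signature starts at the
  rostrum tip and the notch/antirostrum sit at fixed offsets from the
  rostrum, changing the elevation mainly rotates the feature complex around
  the outline; its signal reaches scale 4 only through the interaction with
  the ellipse axes. The five reference shape families (M1–M5) therefore
  differ strongly in the *local* amplitudes scale 4 actually sees (rostrum,
  antirostrum, notch, posterior), on top of upper/lower elevation classes —
  M2/M4 upper-rostrum, M1/M3/M5 lower; M2/M3 subtle vs M1/M4/M5 developed
  antirostrum.
- **Families are tighter than rivers.** Within-family parameter spread is
  half the river-level spread, because a family is one shape class while a
  river population mixes classes. With these defaults, Ward k = 5 on the
  pipeline's adjusted scores recovers the planted families at adjusted Rand
  index ≈ 0.85–0.95.

What the generator does *not* emulate: photographic texture, the sulcus,
segmentation noise beyond rasterization, asymmetric left/right pairs,
age structure, or any real covariance between anatomy axes. Passing tests
therefore demonstrate that the *machinery* recovers planted structure under
its own assumptions — not that real shad rivers are separable at any given
accuracy. Published population-level values (e.g. a survey-wide pseudo-F or
a 90.9% eleven-river accuracy) depend on the real specimens and are treated
as worked examples for the metric definitions, not as reproduction targets.

## Problem sizes and seeds

Desk-scale defaults keep the full pipeline on a synthetic survey (~75–170
otoliths) under a few minutes on one CPU: 999 permutations, LOOCV with a
two-point hidden-unit grid, 3 inner folds and 3 repeats. Publication-scale
settings (9,999 permutations, 1,000 repeats, the full {3, 5, 8, 13, 21}
grid) are plain configuration. One master seed fans out to per-stage seeds
via SeedSequence spawn keys (stage 0 = simulation, 1 = PERMANOVA,
2 = classification, 3 = morphotypes); no stage reads global random state,
and a re-run with the same seed regenerates byte-identical outputs.

## Known limitations

- The contour stage assumes already-binarized masks; grayscale segmentation
  of microscope photographs is out of scope.
- Marching-squares extraction leaves half-pixel boundary wiggle; at
  coarse resolutions this dominates the signature round-trip error.
- The equal-arc resampling is linear between vertices; curvature inside a
  source segment is not recovered.
- Permutation importance on in-sample accuracy is descriptive; correlated
  components split their importance.
- The morphotype PERMANOVA is circular by construction (labels derive from
  the tested matrix) and should be read as effect description only.
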
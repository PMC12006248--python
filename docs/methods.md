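# Methods

## Electric-field model

The forward model is quasi-static conduction, ∇·(σ∇φ) = 0, with Dirichlet
values ±V/2 on the two needle conductors and zero normal flux on the outer
box. This replaces a time-dependent electric-currents model: at the
microsecond pulse widths used, capacitive currents are negligible and
irreversible-electroporation thresholding depends only on the field
magnitude at nominal amplitude.

**Discretization.** Node-centered finite differences on a regular grid
(5-point stencil in 2-D, 7-point in 3-D), face conductivities by harmonic
mean so layered models are handled conservatively. Electrodes are
rasterized as the node set inside each conductor radius; faces crossing the
true conductor surface get a Shortley–Weller cut-cell weight 1/θ (θ = the
fractional distance from the outside node to the surface, clamped at 0.1).
Without this correction the effective conductor radius is inflated by
O(grid step), which biases the whole field several percent low — the error
is largest exactly where treatment planning reads the lethal contour.
Potential gradients use central differences; |E| is reported in V/cm.

**Solver.** Matrix-free conjugate gradients, preconditioned by the exact
inverse of the unmasked constant-coefficient zero-flux Laplacian, which the
type-II DCT diagonalizes (1-D eigenvalues 2cos(πk/n) − 2; the singular
constant mode is regularized to the smallest nonzero eigenvalue). The
preconditioned iteration only has to resolve the electrode constraints and
conductivity contrasts, so it converges in ~15–35 iterations regardless of
grid size (a 241³ solve takes ~2 minutes on one CPU). Convergence is a
relative residual ≤ 1e-6 with an explicit failure if the iteration cap is
reached. Every solve asserts the discrete maximum principle with slack
proportional to the solve tolerance.

**Geometry defaults.** 0.4 mm diameter needles, 4 mm center-to-center
spacing, 4 mm exposed conductor centered on the midplane, 600 V
(a 1500 V/cm voltage-to-distance ratio). The default domain is homogeneous
(0.5 S/m — the distribution of |E| in a homogeneous medium is independent
of the value) with a centered 142 mm³ spherical tumor region; a layered
mode (spheres, slabs, cylinders painted in order) accepts user
conductivities. The bounding box extends 3× the electrode spacing from the
midpoint in every axis. That margin is adequate for coverage near the
electrodes, but the two-wire far field decays only like a 2-D dipole, so
validation against the closed-form bipolar-cylinder solution uses a 12×
box and compares within 1.5× spacing of the midpoint (≥ 1 diameter from
either conductor), where agreement is < 2% in |E|.

**Coverage conventions.** Cells exactly at the threshold count as ablated.
`coverage_curve` exploits linearity of the Laplace problem: one solve at a
reference voltage is rescaled exactly for every ratio in the sweep.
`invert_threshold` maps a measured lesion area to the grid quantile of
sorted |E| values on the solved plane; it is the inverse of the forward
area measurement to within one grid quantile.

**3-D versus extruded coverage.** Two forward models are provided and the
difference between them matters at the few-percentage-point level. The 3-D
homogeneous model treats the exposed conductor as a finite 4 mm segment in
an open domain; field decays along the needle axis beyond the exposure, so
the tumor poles see weak field. In the subcutaneous configuration the
needles pass down through the tumor with an insulating tissue–air boundary
above, which mirrors the conductors and confines current so the field is
approximately invariant along the insertion axis. `extruded_ablation_metrics`
models this limit: a 2-D cross-sectional solve extended along the axis,
with each in-plane point weighted by its chord through the tumor sphere.
For the default geometry the 3-D model gives ~19% coverage at 1077 V/cm
and the extruded model ~23%; the extruded value matches the closed-form
two-wire prediction for the same geometry to ~0.1 percentage point, so the
gap between the two is a statement about axial confinement, not numerics.

**Burst arithmetic.** A bipolar burst (w⁺, delay, w⁻, delay) energized for
T µs contains T/(w⁺+w⁻) cycles; non-integer cycle counts are rejected. The
2-5-2-5 scheme at 100 µs/burst, 200 bursts, 1 Hz gives 25 cycles/burst,
20 ms total energized time, ~200 s delivery.

## IHC quantification

Optical density is −log10(I/I₀) per channel with I₀ the white level
(dtype maximum for integer images); intensities below I₀·10⁻³ are capped at
OD 3 with a warning. Stain separation inverts the 3×3 unit-vector matrix of
the standard published H-DAB basis (hematoxylin, DAB, residual; the same
vectors scikit-image ships); negative concentrations are clamped to zero
after recording the affected pixel fraction. The binarization threshold is
Kapur's maximum-entropy criterion on a 256-bin histogram over the observed
range: choose the split maximizing the sum of background and foreground
Shannon entropies. It depends on the image only through its histogram and
is checked against an independent exhaustive-scan implementation.

Vessel counting labels 8-connected components, drops components below
15 µm² (the same speck floor as the lymph-node pipeline, applied here for
consistency), and attributes a component to an ROI when its centroid lies
inside the polygon (boundary counted inside). Density is vessels per mm² of
ROI polygon area (shoelace); area percent is measured over rasterized ROI
pixels. Pixel coordinates are 0-based, x right, y down.

Picrosirius-red fiber classification works in HSV: pixels above a 0.2
saturation and 0.1 value floor are red-yellow for hue ∈ [0°, 70°) ∪
[330°, 360°) and green for [70°, 170°); all bands configurable since no
standard numeric convention exists. A zero green area yields an infinite
ratio sentinel with a warning. The live/dead lesion is the largest
8-connected component of dead-positive ∧ live-negative pixels, each channel
thresholded by maximum entropy unless given explicitly.

## Lymph-node pipeline

Pixel features are Gaussian-smoothed intensity, Hessian determinant, and
max/min Hessian eigenvalues at scales 2 and 4 px on 0.65 µm/px imagery
(reflective boundary handling). The pixel classifier is a small MLP with
one hidden layer of 5 units on those 8 feature planes, trained on balanced
seeded samples of positive and ignore pixels; a described 3-layer "3-5-2"
architecture cannot accept 8 input planes, so the input width follows the
feature count and the 5-unit hidden layer and 2-class output are kept.
Training is deterministic for a fixed seed.

Objects are traced as iso-contours of the (lightly smoothed, σ = 1 px)
probability map at sub-pixel precision. Smoothing before contouring
matters: marching squares on a raw binary mask yields staircase polygons
whose perimeter overestimates a circle's by up to ~π/2 in the limit —
which is why discretized circle VCIs are often quoted as 1–1.57 — whereas
the smoothed sub-pixel contour of a digitized circle converges to 2πr
within 2% by radius 10 px, keeping the circle at its ideal VCI of 1.
Nested contours are resolved by even–odd depth (holes subtracted from
their smallest enclosing outer boundary). Per-object intensity features
(CD31 mean/median/SD, LYVE-1 mean/SD) are measured inside the polygon on
channels smoothed with a 2.0 µm Gaussian; shape features are circularity
4πA/P² and solidity A/A_hull.

Classification into lymphatic (LYVE-1⁺) versus blood (LYVE-1⁻) uses either
a seeded 100-tree random forest on the seven features or a deterministic
fallback — LYVE-1 mean above background mean + 2 SD — that is always
available for reproducibility. Manual curation steps are replaced by
programmatic equivalents: objects overlapping ≥ 50% of the smaller area are
merged, and objects with CD31 mean below background + 2 SD can be dropped.
The area filter keeps objects with A ≥ 15 µm² (boundary inclusive, as the
stated filter does not specify strictness) and is idempotent.

Node summaries normalize per-class areas to the node polygon minus artifact
polygons; VCI is computed from the formula directly, so its invariants
(scale invariance, additivity over identical shapes, ≥ 1 for a single
convex object) hold exactly.

## Assay calibration

qPCR: ordinary least squares of Cq on log10 concentration over the 7-point
default dilution series (2000…31.125 µg/µl), replicated per plate. The
curve is usable only when R² > 0.9; quantification through an unusable
curve raises. Efficiency is 10^(−1/slope) − 1, so efficiency ∈ (0.9, 1.1)
iff slope ∈ (−3.60, −3.10), and a perfect doubling gives slope
−1/log10 2 ≈ −3.3219. Abundances are normalized to the R18S abundance of
the same sample. Undetectable transcripts are represented as missing, never
zero.

ELISA: 4PL y = d + (a−d)/(1 + (x/c)^b) fitted by Levenberg–Marquardt from
heuristic starts (asymptotes from the extreme responses, c from the
mid-response standard, Hill slope sign from the trend); uniform weights by
default with optional 1/y² weighting. Inversion is the closed form
x = c·((a−d)/(y−d) − 1)^(1/b); signals at or beyond the asymptotes are
flagged with no finite concentration. Tissue normalization is
concentration × eluate volume / tissue mass (pg/mg).

## Cohort statistics

Percent change is 100(V_t − V₀)/V₀ against the volume on the treatment
day (measured before pulsing). The consistency check
100((1 + c/100)(1 − f) − 1) converts a control change c and ablated
fraction f into the expected treated change; it is increasing in c and
strictly decreasing in f. Lognormality is declared per variable (no silent
normality testing); declared-lognormal data are log10-transformed before
testing and summarized untransformed. With two groups, Welch's correction
applies when forced or when the sample-variance ratio exceeds 4 (an
operationalization of "standard deviations unequal"); three or more groups
get one-way ANOVA with Tukey's HSD. Pearson correlation uses the
t-distribution two-sided p value and refuses zero-variance input.

## Synthetic data

The generators emulate the study's inputs, not histology realism: vessels
are elliptical annuli (IHC) or disks (IF) with hard class-dependent
intensities, noise is Poisson shot noise at a configurable photon budget
plus Gaussian read noise, vessel cross-section areas are log-normal
(median 80 µm², σ_log 0.5 — a plausible capillary scale chosen as a fixture
convention), and growth is exponential with log-normal rate, baseline, and
measurement noise. Cohort defaults follow the study design: 7 animals per
arm, 142 mm³ baseline at a day-0 treatment, 135%/day control growth, and a
0.2332 ablated fraction applied after the baseline measurement. Passing
tests on these scenes demonstrates algorithmic correctness (segmentation,
classification, calibration, inversion recover known truth), not
robustness to real staining variability, uneven illumination, or
out-of-focus tissue, which the generators deliberately do not model.
Placement is rejection-sampled with pairwise clearance and fails loudly
when infeasible. Every generator is a pure function of its spec (seed
included): reruns are byte-identical, and each truth sidecar is sufficient
to compute the expected value of every downstream metric.

## Problem sizes

Default analysis sizes were chosen so every stage runs on a laptop-class
machine: 3-D field solves at 0.1 mm (241³ nodes, ~2 min), 2-D solves at
0.025–0.05 mm (seconds), synthetic tiles of 256–512 px for routine runs
with 2048 px available where realism in scale matters, and 10⁴ Monte-Carlo
replicates for test-level calibration checks.
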
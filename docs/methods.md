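# Methods

## Model and procedure

The detector assumes cell nuclei are approximately radially symmetric
intensity blobs whose boundary gradients point (after an optional sign
flip) toward the nucleus center. It makes no assumption about nucleus
*size* beyond an upper bound *r*, none about contrast beyond its sign
(the polarity flag), and — critically for Nissl-stained tissue — none
about the interior being solid: a nucleolus or hollow core leaves the
outer boundary evidence intact, and it is the boundary that votes.

Given an image *I* with per-axis physical spacing, the pipeline is:

1. **Blur** (optional, default on): Gaussian, σ = 2 pixels on the
   finest-sampled axis, scaled per axis by the spacing ratio so the
   physical blur is isotropic. Reflective boundaries, so intensity mass
   is conserved.
2. **Gradient**: second-order central differences in the interior,
   first-order one-sided at boundaries, divided by the per-axis spacing
   so derivatives are per micrometer. Magnitude *M* = |∇I| weights each
   site as a voter; the unit gradient (negated for `dark_cells`) is the
   initial vote direction. Zero-magnitude sites carry a null direction
   and never vote, though they may receive votes.
3. **Iterate** cast → re-orient → narrow until the cone aperture drops
   below one pixel of arc (see the schedule below). The final cast is
   the converged vote field.
4. **Localize**: local maxima of the vote field with minimum pairwise
   separation *r*, then an optional score threshold.

### Vote-cone membership

A site **p** receives the vote of voter **t** with unit direction
**d** iff, in physical space,

    cos∠(p − t, d) > cos(ϕ/2)   and   0 < |p − t| < r.

Both inequalities are strict, and the apex never votes for itself. The
2D angular test and the 3D cosine test are the same predicate, so one
cosine-form implementation (squared, avoiding sqrt and arctan) serves
both dimensionalities; 2D images are processed as singleton-z volumes
with a zero z direction component, which leaves the geometry untouched
and keeps a single compiled code path.

Candidate sites are pruned with the tight axis-aligned bounding box of
the cone-plus-spherical-cap solid. The support of that solid along a
coordinate axis **e** is r·cos(max(0, ∠(d, e) − ϕ/2)), clamped at zero
when the whole cap faces away (the apex is then the extreme point); a
one-nanoradian epsilon pads the lattice rounding so the box is a
guaranteed superset of the strict membership set. Pruning correctness
is asserted against a full-window brute-force scan in the tests, and
the scatter ("project votes") implementation is asserted equivalent to
an exhaustive gather ("collect votes") oracle on random fields.

### Aperture schedule

The aperture starts at ϕ₀ = π/2 — detection is insensitive to the
starting value above ~π/4, so the conservative end is used — and is
halved between iterations. The run stops after the first pass whose
aperture satisfies ϕ < ϕ_t = 1/r_px (r_px = the minimum per-axis cone
length in pixels): by the small-angle approximation the cone arc at
full length is then narrower than one pixel, so a narrower cone cannot
change which lattice sites are reachable. That terminating pass still
executes, because its near-degenerate cone concentrates the votes most
sharply; for r_px = 10 the sequence is π/2, π/4, π/8, π/16, π/32 (five
passes). Voter directions are not updated after the final cast.

Two determinism rules close the remaining ambiguity: vote accumulation
runs in a fixed lexicographic voter order, and the argmax in the
direction update resolves ties to the lexicographically smallest site.
Voters whose cone is empty or scores zero keep their direction — zero
evidence means no update. Magnitudes are never modified, and no vote
weighting beyond *M* is applied (extra weighting schemes measurably do
not help this algorithm).

## Localization and thresholding

A site is a raw peak when its score is ≥ every score in the
(2⌈r⌉+1)-sized window (per axis, physical radius *r*) and positive.
Peaks closer than *r* are resolved greedily by descending score (ties:
lexicographically smallest), which matches cluster-then-keep-highest
semantics for isolated clusters; chained clusters (A near B near C, A
far from C) are resolved greedily in the same order.

Score thresholds: `manual` (inclusive), `otsu` (256-bin histogram of
the raw scores), and `otsu_log` (Otsu on log₁₀ scores, the default in
the CLI pipeline). The log variant exists because the vote score of a
cell grows roughly with its boundary area (r² in 3D), so on images with
mixed cell sizes the raw-score histogram is heavy-tailed and plain Otsu
can place its threshold *inside* the cell population; in log space the
cells form one compact mode well separated from noise peaks. Since the
histogram-based Otsu returns the center of the last background bin, the
class boundary is taken at that bin's upper edge.

The LoG baseline is `scipy.ndimage.gaussian_laplace` multiplied by σ²
(scale normalization), sign-flipped per polarity so centers are maxima,
with the same peak machinery. Default σ = 4 pixels, the best-performing
single scale for this tissue type; its single fixed scale is exactly
why it trails voting on mixed-size, hollow-core content.

## Validation

A detection is a true positive iff it can be matched one-to-one to a
ground-truth center within 0.5·r_max (micrometers). Matching is greedy
by descending detection score; each detection takes its nearest
still-unmatched truth center inside the criterion. Unmatched detections
are false positives, unmatched truths false negatives. The PR curve
sweeps the unique scores as thresholds and is integrated by trapezoid
over recall, anchored at recall 0 with the strictest threshold's
precision; the integrator choice matters little because the curves here
are nearly step-free.

## Synthetic phantoms

The generator emulates two acquisition regimes:

- `kesm_like`: dark cells on a light (0.75) background, radii uniform
  in 3–8 µm, contrast 0.5, 50 cells in 128³ at unit spacing, additive
  Gaussian noise σ = 0.05, minimum center separation 2.2× the mean
  radius, and 30% of cells carry a core of 40% radius at reduced
  contrast — the nucleolus mimic that defeats solid-blob detectors.
- `fluor_like`: bright solid cells (contrast 0.7) on a dark (0.15)
  background, radii 4–7 µm, sparser (20 cells) and cleaner (σ = 0.02).

Cells are placed by rejection sampling (error after 10,000 failed
attempts, with advice to lower the density), rendered with a one-voxel
anti-aliased edge (partial-volume mimicry), then noise is added and
intensities clamped to [0, 1]. Generation is a pure function of the
spec including its seed. An anisotropic variant op slices every k-th z
plane and multiplies the z spacing accordingly, emulating coarser
section thickness.

What the phantoms deliberately do **not** model: unstained vessel
voids and other non-cell dark structure, spatially correlated
(Poisson/speckle) noise, point-spread anisotropy, sectioning artifacts,
and non-spherical somata. Passing tests therefore demonstrate the
geometric and numerical correctness of the machinery and its robustness
to noise, size mixture, hollow cores and anisotropic sampling — not
performance on real tissue, where pre-processing quality dominates.

## Numerical choices and problem sizes

- All geometry is evaluated in physical micrometer space; lattice
  offsets are scaled by the per-axis spacing before any distance or
  angle, which is what makes the radius-in-micrometers interface
  resolution- and anisotropy-independent.
- Strictness of both membership inequalities, the tie rules above, and
  fixed loop orders make the whole pipeline bit-deterministic; the
  test suite asserts byte-identical CSVs across repeated runs.
- Vote-mass bookkeeping is exact: each cast records per-voter member
  counts, and Σ V = Σ_t M(t)·|cone(t)| is asserted to 10⁻⁶ relative at
  every iteration of a full run (it holds to machine precision).
- Degenerate inputs: blank images produce a zero vote field and no
  detections; Otsu on empty or constant score lists raises; cones
  clipped entirely outside the lattice yield empty boxes and member
  sets; a radius below one pixel (or below the coarsest spacing, for
  the full pipeline) is rejected up front.
- Reference problem sizes: the bundled end-to-end experiments use a
  128³ dense phantom (50 cells), its 128×128×64 anisotropic variant,
  and 32³/64² single-cell images — sizes at which the full suite and
  the reproduction script each finish in well under a minute per run
  on one CPU while exercising every code path at realistic density.

## Known limitations

- The minimum-separation rule assumes one radius class; a field mixing
  r = 3 µm neighbors with r = 8 µm cells closer than 8 µm would merge
  true neighbors (the phantoms' separation constraint respects this).
- Hollow-core boundary voters on the *inner* rim vote away from the
  center (their cone never sees it), costing a small amount of score
  and occasionally a weak spurious peak; the log-Otsu threshold removes
  these in practice.
- Very large radii make the per-voter cone enumeration the bottleneck
  (cost ∝ r³ per voter in 3D); down-sampling the image is then more
  effective than enlarging the cone.
- 16-bit and 8-bit TIFFs are rescaled by dtype range, not by their
  empirical min/max; heavily under-exposed inputs should be normalized
  beforehand.
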
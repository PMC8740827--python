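# Methods

This note documents the models, algorithms and numerical choices behind
`minidials`, in the spirit of a methods section: what each stage assumes,
which parameters matter, and what the synthetic test bed does and does not
emulate.

## Geometry and conventions

The laboratory frame is right-handed in mm. By default the beam travels
along +z, the goniometer axis is +x, and the single flat detector panel has
fast axis +x, slow axis +y and plane normal +z. Pixel coordinates are
0-based with integer values at pixel corners (centre of pixel *i* at
*i* + 0.5); bounding boxes are half-open. Angles are degrees at every
interface; image numbers at user interfaces are 1-based inclusive.

The crystal is carried as the UB matrix **A**, whose columns are the
reciprocal basis vectors a\*, b\*, c\* in the laboratory frame (1/Å). The
incident wavevector is s0 = direction/λ with |s0| = 1/λ; a reflection h
diffracts at rotation angle φ\* when |R(e, φ\*)·A·h + s0| = 1/λ. Unit-cell
parameters are always derived from the metric AᵀA, so they are invariant
under any rotation of the crystal.

Roots of the diffraction condition are located by scanning the squared
Ewald offset in 0.1° steps and refining each sign change by bisection.
Because |R·A·h| is constant in φ, the offset is an exact sinusoid
a + b·cos φ + c·sin φ, which the vectorized scan exploits; bisection runs
to an interval of 1e-9°, giving Ewald residuals below 1e-8 per reflection.

## Synthetic data generator

The generator is the package's test bed: it forward-models a rotation
experiment so every stage can be validated by parameter recovery.

* **True intensities** follow the acentric Wilson law: one exponential draw
  per symmetry orbit with mean Σ·exp(−2·B·(sin θ/λ)²), expanded so
  symmetry-equivalent reflections share a value. Defaults Σ = 2000 counts,
  B = 15 Å².
* **Rocking curve**: Gaussian of width σ_m (default 0.3°); each frame
  receives the normal-CDF mass of its rotation interval, so frame
  fractions of an interior reflection sum to 1.
* **Spot footprint**: isotropic 2D Gaussian of sd σ_b·distance·π/180 mm
  on the detector face (σ_b default 0.05°), deposited by pixel-integrated
  CDF differences.
* **Inverse scale** g(φ) = k(φ)·exp(−2·B(φ)·(sin θ/λ)²) multiplies the
  deposited signal. The default planted k(φ) is 1 + 0.3·sin(2πφ/180°)
  (random phase for datasets after the first); the planted decay ramp is
  zero by default.
* **Counting**: per-pixel Poisson over a flat background (2 counts/px),
  clipped at the saturation value; optional planted dead / hot / twinkling
  pixels, a scrambled-intensity outlier dataset, and per-dataset
  indexing-ambiguity operators drawn from the lattice-group coset.

The default desk-scale geometry is a 256×256 panel of 0.2 mm pixels at
150 mm, λ = 1 Å, 180 images of 1°, cells of 38–60 Å. At this geometry the
panel corner reaches only ≈ 4.2 Å, so the effective resolution is
detector-limited; this is intentional — it keeps a full pipeline run in
the low minutes on one core. Scenario-specific conditions are fixed once:

* *two-lattice*: 64×64 px of 0.8 mm at 100 mm, 90 images, a 24–32 Å
  triclinic cell — small enough that the two lattices' predictions are
  separated by several pixels per index step;
* *screening wedge*: 20 images with the detector at 80 mm, so the Wilson
  plot has enough 1/d² lever arm for a meaningful B fit;
* *multi-dataset (cosym / ΔCC½)*: 60-image sweeps, matching the partial
  datasets this analysis exists for.

Table-level simulation (`simulate_intensity_tables`) bypasses image
rendering: predicted reflections receive I ~ Normal(g·I_true,
g·I_true + v_bg), the Gaussian limit of Poisson counting over a spot plus
a flat-background term. Symmetry, cosym, scaling and ΔCC½ operate on
integrated intensities only, so this is the appropriate level of realism
for those stages, at a fraction of the cost.

What the generator does **not** emulate: absorption, radiation damage,
detector point spread beyond the Gaussian footprint, non-Gaussian mosaic
models, ice rings, or multi-panel geometry. Passing tests therefore show
algorithmic correctness under idealized conditions, not robustness to
every pathology of real data.

## Spot finding

Per-image dispersion thresholding over a 7×7 window: a pixel is strong if
the window's index of dispersion σ²/μ exceeds 1 + 6·√(2/(n−1)) (gain 1),
its value exceeds μ + 3·√μ, and it clears a global floor (0). Strong
pixels are grouped into maximal 6-connected components in (x, y, frame);
6-connectivity (not 26) avoids bridging neighbouring lattice spots on fine
slicing. Each component yields a shoebox (bounding box padded by one pixel
of background) and an intensity-weighted centroid. Components smaller than
3 voxels are dropped by default.

## Indexing

Strong centroids map to reciprocal space as r = R(e, −φ)·(s1 − s0). The
basis search bins points onto a 64³ grid covering |r| ≤ 1/d and takes
local maxima of the 3D FFT amplitude (above 0.25 of the strongest
non-origin peak) as direct-space candidate vectors, with parabolic
sub-grid interpolation of peak positions. Because the grid's Nyquist
direct length is grid_n·d/4, the FFT uses only spots at or below the
resolution that resolves the longest plausible axis; that length is
estimated from the median nearest-neighbour spacing of the reciprocal
points unless the user supplies it.

Candidate triples must satisfy volume > 100 Å³ and pairwise angles in
(20°, 160°); each triple is Buerger-reduced (shortest-vector passes) and
rejected if reduction collapses an axis below 3 Å. Triples are scored by
indexed fraction at a selection tolerance of 0.15; among triples within
5% of the best fraction the smallest cell wins — a doubled cell's denser
reciprocal lattice can index everything a true cell does, so raw fraction
alone favours supercells. Assignment then iterates from low resolution
(2× the data limit) inwards, re-fitting **A** linearly at each step, and
finishes with geometric refinement.

The final indexed/unindexed decision compares each spot's observed
centroid with its prediction from the refined model and rejects outliers
at 4.5 robust sigmas per dimension (x, y, φ). This is what separates a
second lattice: its spots can land within the 0.3 fractional-index
tolerance by accident, but they predict to the wrong detector position.
With `max_lattices` > 1 the basis search repeats on the unindexed
remainder.

Lattice symmetry is assessed by the Le Page construction: candidate
twofolds are integer direct/reciprocal axis pairs (u, g) with u·g ∈ {1, 2}
and rotation matrix (2/(u·g))·u gᵀ − I; δ is the angle between the
direct-space axis D·u and the reciprocal-space axis A·g. Accepted
twofolds (δ ≤ 2° by default) generate the lattice point group by closure;
the Bravais class follows from the group order (2 → mP, 4 → oP, 8 → tP,
12 → hP, 24 → cP). Conventional-setting transforms are searched among
proper signed permutations, and a class is only listed when such a setting
brings the cell within ~3× the Le Page tolerance of its constraints —
this suppresses pseudo-symmetric metrics (e.g. a monoclinic cell
accidentally near a centred orthorhombic one, since centred lattices are
out of scope).

## Refinement

Static refinement minimizes weighted centroid residuals (Δx, Δy in mm, Δφ
in deg) over three orientation angles, the symmetry-constrained cell
parameters, the detector origin and its in-plane rotation, using
trust-region least squares with numerical derivatives. Weights are inverse
centroid-variance estimates from counting statistics with floors of
(0.25 px)² and (0.25·Δφ)²; outliers are rejected beforehand at 4.5 robust
sigmas per dimension. The beam stays fixed; the detector's normal offset
is refined only when more than 100 reflections are available.

Scan-varying refinement attaches orientation and cell parameters to knots
every 36° and interpolates with a Gaussian smoother over the three nearest
knots (sd = interval/2). Per-reflection **A** matrices are formed by
smoothing the per-knot **A** matrices elementwise — for the small
inter-knot changes involved this is equivalent to interpolating the
parameters to second order and keeps the evaluation vectorized. Per-image
**A** matrices evaluated at frame centres are exported on the crystal
model.

## Integration

The profile model is two angular widths: σ_b (beam spread on the detector
face) and σ_m (rocking width). Both are estimated from indexed strong-spot
shoeboxes as intensity-weighted second moments — of pixel directions about
the mean diffracted direction, and of the per-frame φ profile about its
centroid. Because a frame (1°) can be several σ_m wide, the naive
Sheppard correction is biased; instead the estimator inverts the exact
phase-averaged variance of a binned Gaussian, which is unbiased for the
generator's Gaussian profiles at any slicing.

Shoeboxes span ±3σ on each axis (so the ±1σ core occupies the central one
third of the box) plus a background ring of 2 px / 1 frame. Background is
a constant per shoebox from iterated mean with 3σ Poisson rejection
(median start, ≤ 5 rounds). Summation integration takes
I = Σ_fg c − n_fg·b̂ with Poisson error propagation including the
background-estimate term.

Profile fitting works on a 9×9×9 grid in the normalized local frame
((x, y) in units of σ_b about the predicted centroid, φ in units of σ_m).
Pixel counts are scattered onto the grid with separable weights that
apportion each pixel's interval by the standard normal measure — so the
grid image of a reflection is independent of its sub-pixel and frame
phase, and the scatter conserves counts exactly (edge overflow folds into
the boundary cells). References are accumulated per 3×3 detector region
from strong reflections (I/σ ≥ 10, relaxed if scarce), clamped
non-negative and normalized. Each reflection's data, background and
variance are transformed to the same grid and the reference is scaled by
weighted least squares; in the zero-background noiseless limit this
reproduces summation exactly. Fits with less than 50% profile overlap
(clipped boxes) fall back to summation and are flagged.

## Symmetry

Every rotation of the metric's lattice point group is scored by the
Pearson correlation of merged intensities related by it (Friedel mates
merged first). The identity is scored on random half-splits of repeated
observations, which calibrates CC_true. Likelihoods use a two-component
normal model, G(CC; CC_true, σ_cc) versus G(CC; 0, 2σ_cc), with
σ_cc = 0.1 so Z-CC = 10·CC; elements with fewer than 10 pairs score 0.5
and are flagged. Closed subgroups are enumerated by breadth-first closure
and ranked by Σ log L(included) + Σ log(1 − L(excluded)), ties to higher
order. The winner is reported as both a Laue ("true") symbol and the
acentric rotation-only group assigned to the output, and the data are
reindexed to a conventional setting found among signed permutations.

`cosym_align` resolves indexing ambiguity across datasets by assigning one
lattice-group operator per dataset to maximize the summed pairwise CC of
shared unique intensities: coordinate descent over assignments with
dataset 0 fixed to the identity, five seeded restarts, best objective
kept. Operators equivalent under the true point group tie up to noise, so
within a small tolerance (0.02 on the objective) the earliest
(identity-first) operator is preferred; the solution is defined up to one
global operator, which is the physically meaningful gauge freedom.

## Scaling and merging

The physical model g = k(φ)·exp(−2·B(φ)·(sin θ/λ)²) uses knots every 15°
smoothed by a Gaussian over the three nearest knots (sd = 7.5°); k is
smoothed in the log so it stays positive. Fitting alternates
inverse-variance merging with a damped least-squares knot update until the
objective is stable (tolerance 1e-6, max 50 rounds; the merge target
refreshes each round, so stability over several rounds is required rather
than monotone descent). Gauge: mean k = 1 and mean B = 0 per dataset — a
constant B is absorbed exactly by the merged means. Two restraints
stabilize the fit: second differences of log k (prior sd 0.1) and the B
values themselves (prior sd 0.3 Å²); the latter is needed because at
detector-limited resolution the (sin θ/λ)² lever arm is short and B(φ)
would otherwise trade freely against k(φ). A linear decay ramp is only
weakly penalized; datasets averaging fewer than 2 observations per unique
reflection have B frozen at 0.

The error model σ'² = a²(σ² + (b·I)²) is fitted by Nelder–Mead from
(1, 0.02) so normalized deviations about the merge means have unit
variance overall and in the top intensity decile.

Merging statistics use the standard definitions; CC½ correlates merged
means of two random halves, with per-observation half labels drawn once
from a seeded generator — so removing a subset and re-adding it reproduces
CC½ exactly, which ΔCC½ (CC½(all) − CC½(without group)) relies on.
Resolution bins are equal-volume in 1/d³. The usable resolution limit is
where a fitted curve c(s) = c0/2·(1 − tanh((s − s0)/r)) crosses CC½ = 0.3;
if it never crosses, the strongest bin edge is reported with a flag.
Iterative scale-and-filter removes the worst group per cycle while its
ΔCC½ is below −0.008, stopping after 5 cycles or at 30% data removed.

## Post-scaling products

Two-theta cell refinement fits the symmetry-constrained cell to observed
scattering angles only (2θ from each centroid's direction against the
beam), so it is independent of the orientation model; esds come from the
inverse normal matrix scaled by the reduced χ², printed with esd-in-
parentheses notation (one significant digit, two when the leading digit
is 1).

French & Wilson amplitudes are posterior means under a Wilson prior
(acentric p(F) ∝ F·e^{−F²/Σ}, centric p(F) ∝ e^{−F²/2Σ}) and a normal
intensity likelihood, integrated by trapezoid with 2000 points on
[0, √(max(I,0) + 10σ)]. For strong reflections (I/σ > 30) the domain is
narrowed to the posterior's support — a fixed grid over the full interval
cannot resolve a width of σ/(2√I). Per-reflection Σ is the bin mean of
max(I, 0) in equal-volume bins. Centricity: h is centric when a
point-group rotation maps it to −h.

Exports are plain text: SHELX HKLF4 (fixed 4-wide integer and 8.2-fixed
fields, all-zero terminator) and a column-headed unmerged format carrying
cell, symmetry and wavelength in comment headers. The processing report is
a single JSON document with per-stage sections, validated against a small
internal schema.

## Detector diagnostics

The overload histogram bins all shoebox pixel values ([0, 5000) in 5000
slots by default). Bad-pixel detection runs the spot threshold per frame
with every signal pixel counted and flags pixels carrying signal on half
or more of the frames (out-of-trusted-range pixels likewise). The pile-up
flux ratio for a Gaussian rocking curve sliced into Δφ frames is

    ratio = Δφ / (σ_m·√(2π)·erf(Δφ/(2√2·σ_m)))

— the peak-to-mean instantaneous flux for a frame centred on the rocking
peak, i.e. the worst case over frame phase (a deliberate choice; the
phase-averaged ratio would be smaller). It tends to 1 under fine slicing
and to Δφ/(σ_m√(2π)) for coarse slicing. The screening tool divides the
detector's trusted maximum by this ratio, fits ln⟨I⟩ = ln K − 2B(sin θ/λ)²
to wedge intensities by weighted least squares, and reports exposure
multipliers to reach ⟨I/σ⟩ = 1 (Poisson σ ≈ √I) at standard resolutions
including 0.84 Å.

## Known limitations

Single flat panel, primitive lattices only (no centring in the Bravais
catalog), no absorption or array scaling model, 3D-FFT indexing only, and
symmetry assignment to the point-group level (no systematic-absence
analysis). Conventional-setting searches cover signed permutations, which
suffices for primitive cells indexed near their conventional basis. The
scan-varying model interpolates **A** elementwise between knots, which is
accurate for the sub-degree, sub-percent variations it is meant to absorb.
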
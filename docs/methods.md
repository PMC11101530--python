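# Methods

## Shape descriptors and the morphology number

Each segmented object is an 8-connected set of pixels with a physical
calibration (µm per pixel). The descriptors follow the conventions of
particle-analysis software for filamentous cultures:

* **Projected area** `A = n_pixels · cal²` (µm²).
* **Elongation** `E = (σ_L / σ_T)²`: the pixel-centre coordinates are
  projected on the principal (orthogonal-regression) axis and its
  normal; `σ_L`, `σ_T` are the standard deviations of those projections,
  ordered so `E ≥ 1`. Equivalently, the ratio of the two eigenvalues of
  the coordinate covariance matrix. `E` is 1 for a disk and grows
  quadratically in the aspect ratio (a filled `a × b` shape has
  `E ≈ (a/b)²`).
* **Solidity** `S` (identical to roughness `R`): object area over
  convex-hull area. The hull is taken over the *corner points* of the
  pixel squares, not the pixel centres — a centre hull systematically
  understates the area of thin objects and would push `S` above 1.
  With the corner convention `S ∈ (0, 1]` up to a small rasterisation
  tolerance; a rasterised disk of radius `r` px has `S ≈ 1 − O(1/r)`,
  reaching 0.98 around `r ≈ 60`.
* **Maximum diameter** `D`: the maximum Feret diameter, i.e. the largest
  pairwise distance between hull vertices of the pixel-square corners,
  times the calibration. A single pixel has `D = cal·√2` by convention.
* **Morphology number** `Mo = 2·√A·S / (√π·D·E)`. For a perfect circle
  the formula cancels to 1; the isodiametric inequality
  (`A ≤ π(D/2)²`) together with `S ≤ 1`, `E ≥ 1` bounds `Mo ≤ 1` for any
  planar shape. Values beyond `1 + 2%` (the rasterisation tolerance)
  indicate an inconsistent descriptor chain and raise an error rather
  than being clamped. A rasterised disk of radius 200 px yields
  `Mo = 0.991`, converging to 1 from below as the radius grows.

Elongation is undefined (raises) when the transversal variance
vanishes — e.g. a one-pixel-wide straight line — or below 3 pixels.

### Classification

The field reports group *ranges* (clumps/hyphae ≤ 164 µm², pellets
10⁴–10⁶ µm²) but no decision rule, so the rule here is a declared
default: objects below a 20 µm² debris floor are `debris`; at
inoculation time (0 h) objects up to 300 µm² are `spore`; otherwise the
pellet/clump boundary sits at `A* = 1000 µm²` — inside the geometric gap
between the two observed group ranges, inclusive on the clump side. All
thresholds are configurable (`ClassThresholds`).

Group summaries report mean, n−1 SD and a Student-t confidence band at
`1 − α` (default α = 0.05) for each descriptor, plus a sufficient-n flag
at the conventional ≥ 30 objects per group.

## Segmentation

Pipeline: median filter (default 3×3, reflect padding) → automatic
bimodal threshold of the filtered intensity (polarity-aware; objects are
dark on a bright background) → Sobel edge-band refinement → optional
hole filling → 8-connected labelling → minimum-area filter → border
policy. 8-connectivity is used because hyphal strands are thin and
frequently diagonal-connected.

The automatic threshold is Otsu's method followed by one isodata step
(recentring the cut at the midpoint of the two class means). The extra
step matters on near-noiseless images: Otsu's between-class variance is
flat across an empty histogram gap and the returned bin centre can hug
the object class, cutting off objects in the upper half of that bin.
A fixed numeric threshold is available for exactly reproducible runs.

Edge refinement adds Sobel-edge pixels whose intensity lies on the
object side of the class-mean midpoint, where contiguous with a detected
object (binary propagation). On hard-edged synthetic scenes this is a
no-op; on smoothed boundaries it recovers the transition band without
inflating noise-free areas.

The minimum object area defaults to 20 µm² (suppresses specks, keeps
small hyphal fragments). Raising it to 100 µm² also removes 10 µm talc
microparticle distractors (disk area π·5² ≈ 78.5 µm² < 100) — how the
original studies excluded talc from the measured object sets is not
described, so this filter is the package's own mechanism. Objects
touching the image border are excluded by default (their `A`, `D`, `E`
are biased); a flag-only policy is available.

Accuracy expectations, measured on synthetic scenes: for non-touching
objects of ≥ 500 px on noise-free scenes, counts are exact and areas
within 2% of truth; with Gaussian noise of sd up to 5% of the
object/background contrast, areas stay within 5%. Thin filaments near
the minimum-area boundary can lose a pixel or two to the median filter,
so strict count recovery is only claimed for the large-object regime.

## Enhancement factors

`EF = mean(treatment) / mean(control)` over replicates, per metabolite,
sampling time and talc condition. The confidence band uses the delta
method on `log EF` with treatment and control means treated as
independent — `var(log EF) ≈ s_t²/(n_t m_t²) + s_c²/(n_c m_c²)` — and a
Student-t quantile at `min(n_t, n_c) − 1` df; the original reports show
EF error bars without stating a formula, so this propagation is a
declared choice. The accompanying p-value is a two-sided Welch t-test on
the replicate amounts (group sizes and variances differ across
conditions; a pooled-variance variant is available). EF is exactly
scale-invariant, so it applies equally to absolute concentrations
(mg L⁻¹) and arbitrary-unit ion-peak areas.

With 4 replicates and lognormal replicate noise at CV 0.1, the EF
estimator recovers a true 9-fold effect to within 5% in expectation
(the ratio-of-means bias is `O(CV²/n)`). Rank order across conditions
is reliably recovered only for effects separated by ≥ ~50%; near-tied
true EFs (e.g. 2.0 vs 2.5) cannot be ordered dependably from n = 4 at
this noise level, which is a property of the design, not the estimator.

## Glucose uptake rates

The per-time replicate means of the glucose concentration are fitted
with a cubic B-spline with knots at the data times; the uptake rate is
the negative analytic derivative of the fit, reported positive for
consumption (g GLU L⁻¹ h⁻¹). With knots at all data times a
least-squares cubic B-spline degenerates to interpolation, so
interpolation is the default; a smoothing variant (configurable penalty
weight, for noisy replicate means) is provided.

Boundary conditions: the default is not-a-knot, which reproduces cubic
polynomials exactly; a natural-spline option (zero end curvature) is
available but deviates near the ends whenever the underlying curve has
non-zero end curvature, so it is not the default. By construction the
rate integral over the fitted domain equals the total concentration
drop between the first and last means (mass balance, verified to 1e-6
relative in tests). Cubic interpolants of steeply-kneed monotone data
can oscillate between knots; the generator's default curves are chosen
smooth enough that rates at the data times remain non-negative, and
interior oscillation is documented rather than asserted.

## Replicate statistics

`mean_sd_ci` returns mean, n−1 SD and the band
`mean ± t(1−α/2, n−1)·SD/√n` (α default 0.05); for a single observation
dispersion is reported unavailable. `t_test_p` is a two-sided Welch
test; two exactly constant samples yield the documented convention
p = 1 (equal means) / p = 0 (different means). Calibration, verified by
simulation at n = 4: type-I error 0.05 ± 0.01 and 95% band coverage
within ±1% over 10,000 draws.

## The synthetic-data generator

**Scenes.** Objects are rendered dark on a bright background
(phase-contrast-like polarity) with additive Gaussian noise clipped to
the valid range. Pellets are star-convex blobs: a radial profile
`r(θ) = r₀(1 + a·f(θ))` with `f` a normalised sum of random low-order
harmonics (orders 2–6), amplitude `a ∈ [0, 1)`, stretched by
`√aspect : 1/√aspect` (area-preserving) and randomly rotated — smooth,
connected, seed-reproducible irregular outlines whose analytic area
`½∫r(θ)²dθ` is recorded as ground truth. Spores and talc distractors are
small disks (talc at the manufacturer's 10 µm mean diameter, rendered at
higher contrast); clumps/hyphae are gently curved stamped paths of given
arc length and width with at most one short side branch — for these thin
rasterised shapes the rendered pixel count is recorded as the truth,
since no closed-form area exists. Placement is bounded rejection
sampling with a 2 px separation margin; an overcrowded spec raises,
naming the class. Default shape ranges keep pellets inside the observed
10⁴–10⁶ µm² band and clumps below 164 µm².

**Time series.** Five sampling times (0–96 h every 24 h), four
replicates, talc at 0/0.5/5/10/12 g L⁻¹. Amounts are
`control mean × true EF × lognormal multiplier` with unit-mean
multiplicative noise at a configurable CV (default 0.15 — typical
shake-flask replicate scatter; the original reports do not state one).
The true-EF table peaks at 72–96 h with the reported dose response
(oxytetracycline 9-fold at 5 g L⁻¹, its 2-acetyl-2-decarboxamido
derivative 7-fold, milbemycin A3+4[O] above 3-fold at 10 g L⁻¹,
rimocidin unchanged, two metabolites suppressed); unreported
condition/metabolite pairs carry modest plausible values. Glucose
depletes from 22 g L⁻¹ (the medium recipe) to the reported per-condition
96 h concentrations along a power law `c₀ − (c₀−c_f)(t/96)^p`. The
exponents are `p = 3` for the fast-consuming control and 0.5 g L⁻¹ runs
and `p = 1.0–1.2` for the talc-slowed runs: exponents steep enough to
reproduce the reported *final rates* (~1.16 g L⁻¹ h⁻¹) concentrate
essentially all consumption into the last sampling interval, which a
cubic spline on a 24 h grid cannot track monotonically; the defaults
trade exact end-rate emulation for spline-representable smoothness while
keeping the qualitative ordering (control fastest, heavy talc slowest).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: optical realism (halos, defocus, uneven
illumination), touching/overlapping objects (no watershed splitting is
implemented), pellet growth kinetics linking the time points, talc
embedded inside pellets, and LC-MS peak integration upstream of the
amount tables. Bit depth and magnification of the original images are
undocumented; the generator declares its own defaults (unit-range
intensities written as 16-bit TIFF, 1 µm/px).

## Determinism and numerics

Every generator output is a pure function of its spec (which includes
the seed); the pipeline derives per-stage, per-item seeds from the
single config seed via `SeedSequence`, so a full rerun with the same
configuration writes byte-identical CSVs. Rasterisation tolerance is 2%
throughout (disk area, `S`, `Mo` bounds); the degenerate-elongation
floor is 1e-9 px² of transversal variance; descriptor/oracle agreement
is required to 1e-9 relative on masks up to 400 px.

## Problem sizes

Default demo: three conditions × three times, 768² px scenes, three
pellets (plus clumps in talc runs, 35 spores at 0 h) per scene, and the
full five-condition, four-replicate time-series design. The randomised
descriptor suite uses 500 masks spanning all four shape families. These
sizes resolve every claimed property while keeping a complete run in
seconds on one core.
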
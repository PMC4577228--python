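# Methods

## Model and coordinate conventions

The treatment head is reduced to a 2-D x-z cross-section through one leaf
pair of a single-focused MLC.  The origin is the isocenter, z increases
toward the source, the scoring plane is z = 0 and the (point or extended)
source lies on the plane z = SAD.  The collimator middle plane sits at
z = SAD − SCD; with the default constants (SAD 100 cm, SCD 46 cm, leaf
height 8 cm) the leaf slab spans z ∈ [50, 58] cm.  SCD is read as the
distance from the source to the *leaf middle plane* — the only reading under
which the mechanical back-projection x_E = x_N·SCD/SAD is exact.

A leaf cross-section is a circular arc of radius R (R ≥ leaf_height/2, as on
clinical leaves) joined to flat top/bottom faces, with the body extending a
finite `body_extent` (default 20 cm) behind the tip corners.  The leaf body
is physically semi-infinite; 20 cm is a numerical stand-in, safe because the
slab transmission floor e^(−μ·lh) ≈ 4.6·10⁻⁴ makes anything beyond a few
centimetres invisible in the fluence.  The canonical leaf is right-bank
(body toward +x, arc bulging toward the field); the left bank is its exact
mirror and all positions/offsets negate under mirroring.

The source-to-arc-center distance is the Euclidean D = √((x_S−x_C)² +
(z_S−z_C)²), and the tip corners U, V sit at x_C − √(R² − (lh/2)²) on the
top and bottom faces.

## Analytic edge constructions

**Light-field edge (G).**  The grazing ray from the source touches the arc
where (T−S)·(T−C) = 0 with x_T < x_C; the tangency is computed in closed
form (tangent from an external point).  If the tangency height leaves the
leaf slab, or the source lies inside the arc circle, the grazing point
clamps to corner U (above) or V (below).  G is the projection of that point
onto z = 0.  This equals the minimum source-projection over the whole
outline, which is how the tests verify it (10⁵ outline samples).

**Radiation-field edge (P), half-value-layer rule.**  P is the z = 0
intercept of the secant ray whose in-leaf chord AB has length
L = −ln(0.5)/μ (0.722 cm for μ = 0.96 cm⁻¹), i.e. the ray with exactly 50%
primary transmission.  The system {A, B on the arc; S, A, B collinear;
|AB| = L} is parametrised by two arc angles and solved with scipy's hybrid
(Powell) root finder, initialised from the tangency shifted by ±L/2R along
the arc.  If the proximal endpoint lands above the slab (or D ≤ R) the
system is re-solved with A on the flat top face; if the distal endpoint
lands below the slab, with B on the flat bottom face.  Every solution is
verified post hoc against the exact ray-path geometry (|path − L| ≤ 10⁻⁶
cm); a closed-form fallback (the tangent from S to the concentric circle of
radius √(R² − (L/2)²), valid while the chord stays on the arc) guards
against solver failure and doubles as an independent oracle in the tests.

P is defined as the z = 0 intercept of the secant line: the secant
construction fixes a ray, and its scoring-plane intersection is the only
position on that ray at measurement depth.

**Offsets.**  LPO = (G−N)·10, RFO = (P−G)·10, PNO = (P−N)·10, all in mm;
PNO = LPO + RFO holds identically.  The single summary "analytic RFO" for a
radius is the mean over nominal positions −20…20 cm in 1 cm steps — the
curve is flat to < 0.02 mm for R = 15 cm, so mean, central value and plateau
read-off agree to ~0.01 mm.

## Primary-fluence ray tracing

The simulator computes relative primary energy fluence as a weighted beam
integral: for scoring position x,

  Ψ(x) = ∫ φ(s) · exp(−μ·[path through studied leaf + path through opposing
  leaf]) ds / ∫ φ(s) ds,

with φ a Gaussian focal-spot profile (FWHM 0.5-3 mm, truncated at ±4σ).
Path lengths are exact: the leaf region is convex in the x-z plane, so every
ray meets it in one segment found from the circle-line intersection clipped
to the slab and body extent.  The opposing leaf is the mirrored twin placed
so the nominal edges are `gap` = 10 cm apart (a 10 cm square field edge);
only the studied edge's ±3 cm neighbourhood is analysed, on a 0.01 cm grid.

Deliberate physics reductions: monoenergetic primaries with a single
μ = 0.96 cm⁻¹ (no spectrum), no Compton scatter or electron transport, no
inverse-square or divergence weighting (both cancel to first order under
plateau normalisation over the narrow window), 2-D transport only, no
tongue-and-groove or interleaf leakage, diaphragms retracted.  The model is
therefore a *primary-fluence* account of the edge; a full Monte Carlo
treatment adds scatter, which mostly rescales the penumbra tails.

**Quadrature.**  The transmission as a function of the source abscissa has
square-root kinks where the ray family grazes the arc (tangency) and slope
breaks at the tip corners; a global Gauss-Legendre rule therefore stalls
near 10⁻³ accuracy.  The integral is instead split per scoring point at the
exact tangency and corner abscissae (closed-form solutions of a quadratic),
each smooth panel integrated by Gauss-Legendre, and panels adjacent to a
tangency mapped through s = k ± u² so the integrand becomes smooth.  With
the default 201-node budget the profile values are converged to ~10⁻⁹;
doubling the budget changes them below 10⁻¹³.  A `montecarlo` mode samples
source abscissae instead (seeded), reproducing the noise character of a
stochastic transport run; it agrees with quadrature within Monte Carlo
standard errors.

## Edge analysis

Profiles are normalised so the open-field plateau reads 1.  The plateau
level is the mean of all samples within 5% of the 95th percentile — the
whole plateau band, not just its upper tail — so additive noise does not
bias the level upward (a top-tail estimator inflates the plateau by ~2
noise standard deviations and drags every crossing field-ward).

The edge window spans relative intensities 0.02-0.98, grown contiguously
outward from the steepest-gradient sample and padded by 0.3 cm on each
side; growing contiguously keeps isolated noise excursions far out on the
plateau from stretching the window.  Within the window an n-peak Gaussian
mixture (default n = 3, following commissioning practice; an `auto` option
picks n ∈ {1,2,3} by RMSE with a 1% improvement threshold) is fit by
bounded least squares with an analytic Jacobian.  The fit is multi-start:
the first start is edge-aware (a broad peak holding the plateau shoulder
plus narrower peaks spread down the fall, the structure real commissioning
fits converge to), followed by up to nine seeded jittered restarts, with
early stopping at RMSE ≤ 2·10⁻³ or after three stale restarts.  Without the
edge-aware start and the analytic Jacobian, random restarts frequently land
in poor local minima that bias the fitted edge by ~0.1 mm.

The field edge is the 50% crossing and the penumbra width the 20-80%
crossing distance, found by dense sampling plus Brent refinement (10⁻⁹ cm);
raw profiles use monotone piecewise-linear interpolation instead of the
fit.  If noise produces several crossings, the one nearest the
steepest-descent point wins.  The mixture cannot represent the plateau
(all its components decay), so crossings are only ever searched inside the
edge window.  For noiseless simulated profiles the fitted and raw edges
agree within 0.01 mm; fit-based edges are the default, mirroring how noisy
measured or Monte Carlo profiles must be processed.

## Underestimation of the offset by the half-value rule

For a point source the 50% transmission crossing *is* the half-value secant
(the tests confirm agreement to 10⁻⁴ cm).  For an extended source the rule
systematically underestimates: the sagitta between the half-value chord and
the arc is at most R − √(R² − (L/2)²) ≈ 0.016 cm even at the minimum
clinical radius R = 4 cm — small against 1-3 mm focal spots — so splitting
the source into a field-side part (weight ≈ 1), a central part (weight 0.5
by construction) and a shadow-side part (weight < 0.5) gives a fluence at
the analytic edge strictly above 0.5 whenever the source is symmetric.
The true 50% point therefore lies further into the shadow.  The ray-traced
profiles quantify the shift: ~0.14 mm for R = 15 cm with a 1 mm FWHM
source, near-constant across the field.

## Synthetic fixtures

`generate_fixture` produces three deterministic profile families used
throughout the tests: `erf_edge` (the exact penumbra of a Gaussian source
behind an ideal absorber, 0.5·erfc((x−e)/σ√2), with closed-form 50% edge
and 20-80 width 2·z₀.₈·σ and optional seeded additive noise), `step`
(ideal edge), and `reference_mixture` (a published-style three-peak
coefficient set for a simulated R = 10 cm edge whose 50% crossing sits at
9.932 cm).  The erf fixtures emulate the *shape* and noise level of
processed beam data but not correlated Monte Carlo noise, beam-hardening
or scatter tails — passing recovery tests therefore demonstrates unbiased
edge extraction for edge-shaped data, not full measurement realism.

## Problem sizes and defaults

Sweeps default to radii {4, 6, 8, 10, 15, 20, 25} cm, source FWHM
{0.5, 1, 2, 3} mm and nominal positions −20…20 cm in 1 cm steps, the
condition grid of the study the package reproduces; the summary statistics
in the README and the acceptance script use the full 41-position nominal
sweep at the quoted radius and source size.  Tests exercising the whole
radius grid thin the nominal axis (5 cm steps), which leaves every
qualitative conclusion (U-shapes, the R = 15 cm optimum) unchanged.

## Known limitations

* Primary fluence only: simulated RFO values sit ~0.02-0.03 mm below full
  Monte Carlo transport results for the same geometry, the residual being
  phantom/collimator scatter that is out of scope here.
* Single leaf pair; no dosimetric leaf gap between opposing leaves, no 3-D
  leaf side structure, no spectrum or angular source distribution.
* The Gaussian-mixture edge model has an intrinsic residual (RMSE ~5·10⁻³
  against ray-traced edges); its 50% crossing is still accurate to ~0.01 mm,
  but individual coefficients are not physically meaningful.
* The half-value-layer constructions assume the arc spans the full leaf
  height (R ≥ lh/2); smaller radii raise an unsupported-geometry error.
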
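# Methods

## The screening procedure

The package operates on the 2-simplex of three-component mixtures
(fractions a + b + c = 1), embedded as the unit-edge equilateral triangle
with vertices at (0,0), (1,0) and (1/2, √3/2) so that figure sizes and
distances are ordinary Cartesian lengths. Fractions are the single
internal representation; percentages appear only at I/O boundaries
(written with two decimals), which avoids unit bugs and keeps display
rounding out of the arithmetic.

Stage 1 prepares the simplex centroid (sample 1) and the six vertices of
a hexagon of radius `hex_radius` around it (samples 2–7, at angles
`hex_rotation + k·60°`). Each prepared mixture is scored with a scalar
desirability in [0, 1]: the geometric mean of three linear ramps that are
1 inside the specification (size < 50 nm, PDI < 0.15, transmittance
> 99%) and decay to 0 at hopeless values (200 nm, 0.35, 85%). The
geometric mean makes any single hopeless response veto the mixture, which
matches how a formulator reads a response table. Mixtures that never
emulsified score 0.

The designated area of interest (DAOI) is formalized as the
desirability-weighted Cartesian mean of the `top_k` (default 3) highest
scoring samples; samples tied with the k-th score are all included, so a
perfectly uniform stage recovers its own center exactly. The DAOI
direction is the unit vector from the stage-1 center toward that weighted
mean, with a deterministic fallback to angle 0 when the two coincide.
Identification requires at least three samples with nonzero desirability:
fewer means the design has essentially no gradient information, and the
loop stops with `exhausted` rather than guessing.

Refinement places a figure at the DAOI centroid, oriented along the DAOI
direction, with characteristic edge `edge_length` (default: the hexagon
radius, so both stages probe the same length scale):

- *parallelogram* — a rhombus spanned by the direction vector and its
  60° rotation: 4 mixtures, ids continuing at 8;
- *trapezoid* — a wide side (1.5·edge) centered on the anchor,
  perpendicular to the direction, a narrow side (0.75·edge) one edge
  ahead, plus 0–2 evenly spaced extra mixtures per parallel side
  (5–7 mixtures total).

Figures whose vertices leave the simplex fail loudly by default — silent
clipping would change experiment counts; the screening engine enables
`shrink_to_fit`, which scales the figure toward its anchor in 5% steps
until valid, because a closed loop must be able to proceed near the
simplex boundary.

The run stops at the first refinement stage containing a
specification-passing sample; stage-1 near-misses never end the run. The
winner is chosen by `select_best`: among passing samples, lexicographic
on grade (ascending), PDI, size, then transmittance (descending), with
sample id as the final deterministic tie-break. Grade is not part of the
three-criterion pass/fail, but it leads the ranking — a grade-I passing
mixture beats a grade-II one. All specification comparisons are strict:
a size of exactly 50.0 nm fails, a transmittance of exactly 99.0% fails.

Default `max_stages` is 3; both bundled campaign fixtures ended at
stage 2, so behavior beyond the second refinement is an extrapolation
(re-identification of the DAOI then uses all observations to date).

## Formulation bookkeeping

The drug load is `f · mean(c_s) · 0.1` percent, with `c_s` in mg/g over
the individual components and `f` a drug-specific factor (0.7 and 0.5 in
the bundled campaigns). The 0.1 factor is applied literally as the
equation is stated (mean solubility in mg/g divided by 10 gives percent).
The load is computed once per campaign and held fixed across all design
points. Blend axes (e.g. Tween 80 : d-TPGS at 8:1 or 5:1 w/w) are split
by their ratio after the simplex fraction is scaled by
`100 − drug_load`; mass is conserved to 100.00 and the original simplex
point is recoverable by removing the drug and renormalizing.

## Mixture regression

Responses are fitted to main (x_i), interaction (x_i·x_j) and quadratic
(x_i²) terms. On simplex-constrained data mains are exact linear
combinations of the interaction + quadratic columns, so the full term set
is rank deficient; the fit goes through statsmodels OLS, whose
pseudoinverse solve returns the minimum-norm coefficient vector in that
case, and a pseudo-component transform
(x'_i = (x_i − L_i)/(1 − ΣL)) is available for conditioning constrained
regions. R² is reported against the response mean (1 − SSE/SST), defined
as 0 for a constant response. Confidence intervals are t-based at
`alpha` = 0.95 by default; a term is *significant* when its interval
excludes zero, the standard reading of a coefficient plot.

Mixtures that never emulsified are imputed with deliberately pessimistic
worst-case values before fitting — 300 nm, PDI 0.5, transmittance 70%,
grade V by default, all configurable and flagged on the records — so the
fitted surface is penalized in the failure region. Outliers are rows
whose externally studentized residual exceeds 2.5 (configurable); the
mechanism flags and excludes nominated rows but deliberately does not try
to reproduce any particular historical outlier list, since no rule for
those exclusions is documented. Emulsification grade is modeled as an
ordinal-coded numeric response (1–5). Contour grids evaluate the fitted
surface on a triangular lattice (`resolution` points per edge) and assign
equal-width bins over the predicted range; a numerically constant surface
(range ≤ 1e-12 relative) collapses into bin 0.

## The simulator

The simulator is the ground truth for closed-loop testing, not a physical
model of emulsification. Droplet size is a paraboloid
`base + curvature·d²` in Cartesian distance d from the optimum
composition; PDI increases linearly with size above base (clamped to
[0.01, 1]); transmittance is `100·logistic((midpoint − size)/steepness)`
(midpoint 100 nm, steepness 11 nm, so the >99% region closes near the
50 nm size target, coupling the two specifications the way clarity and
droplet size couple in practice); grade follows fixed thresholds (I if
size < 50 and transmittance > 99; II if transmittance > 98; III if > 90;
IV otherwise; V in the failure region, where component-1-rich mixtures
form no emulsion). Measurement noise is Gaussian per response (SD 0.5 nm,
0.01, 0.2%), with each point's stream derived from (seed, composition) so
design-order changes never shift the noise; triplicate observation with
mean ± SD mirrors standard DLS practice.

Presets: `celecoxib_like` places the optimum between the center point and
one hexagon vertex (base 24 nm, curvature 4800 nm per unit²), so stage 1
near-misses the targets, the DAOI lands between samples 1 and 6, and a
single parallelogram refinement contains a passing mixture — 11
experiments. `fenofibrate_like` (base 18 nm, optimum toward the opposite
vertex pair, trapezoid with extras (2, 1)) ends at 14. The passing points
sit ≥ 5 noise SDs inside every threshold, so the counts are
seed-independent. `infeasible` has a 60 nm size floor with a gentle bowl:
desirabilities stay nonzero (the loop keeps refining to `max_stages`) but
no composition can pass. What passing tests show is that the *strategy*
finds optima of smooth single-optimum surfaces efficiently; real response
surfaces can be multimodal, anisotropic and non-smooth at phase
boundaries, and nothing here predicts real formulation behavior.

## Problem sizes and numerics

The test suite and the acceptance script run closed loops of 11–21
simulated experiments, property checks over 50 random admissible surfaces
(optimum within one hex radius of a stage-1 point, feasible disc wider
than the refinement edge, ≥ 3 responsive stage-1 points), 100-instance
fit-vs-normal-equations comparisons at 1e-8, and 200-replicate
coefficient-recovery simulations at n = 30, σ = 2; everything completes
in a few seconds. Point validation tolerates a 0.5% relative deviation of
the composition sum (gravimetric slack) and normalizes exactly;
coordinate round-trips hold to 1e-9. Ranking ties break by sample id,
solubility ties alphabetically — all orderings are deterministic.
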
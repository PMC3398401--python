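# Methods

## The model

`gapcircuit` implements the classical gene-circuit model of the four
trunk gap genes *hb*, *Kr*, *gt* and *kni* in the syncytial blastoderm of
*Drosophila melanogaster*. The state is the protein concentration
v_i^a(t) of gene *a* in nucleus *i* (relative units on a 0–255 scale),
on a one-dimensional anterior–posterior lattice between 35% and 92% egg
length (%EL). Each nucleus obeys

    dv_i^a/dt = R^a χ(t) g(u_i^a) − λ^a v_i^a
                + D^a(n) [(v_{i−1}^a − v_i^a) + (v_{i+1}^a − v_i^a)]

with regulatory input

    u_i^a = Σ_b T^{ab} v_i^b + m^a v^Bcd(x_i)
            + E^{a,Cad} v^Cad(x_i, t) + E^{a,Tll} v^Tll(x_i, t) + h^a.

`g` is the sigmoid g(u) = ½(u/√(u²+1) + 1), the standard regulation
function of this model family; the model text it derives from only
requires "a sigmoidal graph", so the explicit form is a package
convention. χ(t) gates synthesis off during mitosis. Diffusion terms at
the first and last nucleus drop the missing neighbour.

The **shorted model** neglects diffusion and the Tll input (Tll is
inactive between 37% and 57% EL, the window containing the posterior
border of the anterior *hb* domain). This decouples the lattice into
independent four-dimensional dynamical systems parameterised by the local
Bicoid and Caudal concentrations. After the end of time class T6 of cycle
14A the Cad input and χ are frozen, so the shorted system is autonomous
from then on; the phase-space analysis (equilibria, basins, manifolds)
addresses that autonomous system.

### Timing and lattice conventions

* Cycle 13 starts at t0 = 0; interphase 13 = [0, 16.0) min; mitosis 13 =
  [16.0, 21.1) min (χ = 0); cycle 14A = [21.1, 71.1] min, divided into
  eight equal time classes T1–T8 of 6.25 min. Gastrulation time
  τ = 71.1 min; T6 ends at 58.6 min. All configurable via
  `MitosisSchedule`.
* Cycle-13 nuclei sit at odd-integer %EL; at division each parent at p
  produces daughters at p and p+1 (both copying the parent state),
  daughters beyond the posterior bound of the full domain are dropped.
  This is the unique simple convention that reproduces the canonical
  nucleus counts: 30 (cycle 13) and 58 (cycle 14A) nuclei on 35–92% EL,
  and 11/22 on 37–57% EL.
* Integration uses LSODA with dense output, restarted at every χ
  discontinuity, at the T6 freeze and at the division event; default
  rtol 1e−8. States are never clamped; a negative concentration beyond
  1e−6 raises a diagnostic instead of being silently truncated.

## Bcd ensembles

Per-embryo Bicoid gradients are summarised as exponentials
v^Bcd(x) = A e^{−lx}. Two normalization routes are provided for raw
intensity profiles:

* **basic** — subtract a user-supplied quadratic background q(x) and
  floor at zero. (Estimating q from null-mutant staining is out of
  scope; synthetic tests supply the generating coefficients.)
* **variance-minimizing** — per-embryo scale s_j and constant offset
  b_j chosen to minimise the across-embryo variance of s_j(raw_j − b_j)
  on a common grid, under the gauge that the ensemble grid-mean is
  preserved (otherwise s → 0 is optimal). The optimiser alternates
  closed-form affine matches of each profile to the current mean
  profile, iterated to an objective change below 1e−10. This is a
  faithful surrogate for the published variance-minimizing method, whose
  exact weights and grid are not specified in the source material.

Exponential fits use log-linear regression on strictly positive samples
followed by one nonlinear least-squares polish; a profile is flagged
non-exponential when the log-linear R² falls below 0.9 (configurable),
an explicit surrogate for the published but unquantified rejection rule.
Unbiasedness of the fit holds on the x-range where signal dominates
noise; including the truncated positive-only far tail biases both
estimates upward, which is why recovery tests restrict the fit range.

The **median profile** is the member whose (A, l) is nearest (Euclidean,
after standardising each coordinate) to the ensemble centroid, with ties
broken by smallest embryo id. **Threshold positions** are
x = ln(A/c)/l; the reference concentration c is, by package convention,
the median profile's concentration at the median-model *hb* border.

## Phase space

Equilibria of the autonomous shorted system are found by multistart
Newton root finding (scipy `hybr` with the analytic Jacobian) from a
deterministic grid — 5 points per gene axis over [0, 1.2·max(R/λ)] plus
200 Halton points, with optional warm starts — merging solutions closer
than 0.5 concentration units and keeping those with residual below
tolerance. This deliberately replaces numerical continuation (AUTO): it
is reproducible, dependency-free, and adequate at the problem sizes the
package targets; the cost is that equilibria can in principle be missed
between starts, which the tests bound by comparing against exhaustive
enumeration on closed-form toys and by doubling the multistart density.

Stability comes from the analytic Jacobian
J^{ab} = R^a g′(u^a) T^{ab} − λ^a δ^{ab}; an equilibrium is an attractor
when all eigenvalue real parts are < −ε_h, a saddle_k with k positive
real parts otherwise, and non-hyperbolic when any |Re λ| ≤ ε_h = 1e−6.
Each state gets a qualitative code over {0, X, 1} per gene with
thresholds 50 and 150 units. The recurring codes map to conventional
attractor names (1000/10X0/1010 → A1, 1100 → A2, 0100 → A3, 0000 → A4,
0101 → A5); A1 is the attractor whose *gt* component varies continuously.

The Bcd–Cad plane scan finds equilibria at every grid node
(warm-started from neighbours), matches attractor labels between
neighbouring nodes by nearest state — the operationalisation of the
visual label continuity in the source analysis — and emits a boundary
segment wherever a labelled attractor appears or disappears. The
segment is typed saddle-node when the disappearing attractor's critical
eigenvalue is real, Hopf when it is a complex pair; Bogdanov–Takens
points are only reported as intersections of such segments (no
normal-form analysis, and oscillatory attractors are outside the basin
analysis by design). Ambiguous matches flag the node rather than guess.

1-D unstable manifolds of saddles with a single unstable eigenvalue are
approximated by integrating the autonomous flow forward from S ± εŵ
(ε = 0.1 units along the unit unstable eigenvector ŵ), until the flow
stalls at an attractor or t_max = 500 min.

## Basins on Ω

Biological initial conditions form the segment
Ω = {0 ≤ v^Hb ≤ 100, v^Kr = v^Gt = v^Kni = 0}. A basin partition at one
position draws uniform Hb levels on [0, 100] (seeded, counter-based,
bitwise reproducible), integrates each through the nonautonomous
protocol and on until the autonomous right-hand side sup-norm falls
below 1e−6 (or 1000 min elapse), and assigns endpoints to attractors
within a capture radius δ_A = 1 unit. Interval boundaries between
opposing samples are sharpened by bisection (default tolerance 1e−3 on
the Hb axis); bisection is the package's addition beyond Monte-Carlo
resolution and can be disabled. All samples are integrated in stacked
batches (one adaptive solve for hundreds of independent 4-D systems),
which is what makes ensemble-scale basin analysis affordable on one CPU.

Because the protocol is nonautonomous before T6, the computed partition
is the basin decomposition *of the developmental protocol*, not of the
autonomous flow; the two differ (mitotic decay shifts boundaries), and
the toy-system oracle therefore uses an explicit `protocol="autonomous"`
mode in which the partition provably coincides with the autonomous
basins and can be checked against the closed-form separatrix.

Boundary values at successive nuclei are joined by linear spatial
interpolation into continuous boundary curves; crossings with the
maternal Hb gradient are bracketed on a fine grid and polished by Brent
root finding to 0.01%EL.

## Borders, labels, response curves

* **Shorted-model border**: the solution is rough in space, so the
  border is the anteriormost downward half-max crossing of the linearly
  interpolated Hb profile at τ, with half-max defined as half the window
  maximum (absolute saturation varies between parameter sets). The
  border nuclei are the lattice nuclei flanking the crossing.
* **Full-model border**: the solution is smooth, so the border is the
  inflection (zero of the second derivative) of a cubic spline, searched
  within ±3%EL of the half-max crossing to avoid spurious cubic
  wiggles; a profile with no genuine curvature sign change falls back to
  the half-max crossing with a warning.
* **Mechanism label** (AA/AM/MA/MM): each border nucleus is classified
  "attractor" if its solution endpoint at τ lies within δ_A = 5 units of
  a point attractor, else "manifold" if within δ_M = 5 units of a traced
  unstable-manifold branch, else ambiguous. The δ values are explicit
  surrogates for a visual closeness judgement and are configurable.
* **Transition and family**: the attractors owning the initial Hb level
  in the two border nuclei give a (from → to) pair; A1→A3 and A2→A3
  (hb-ON to hb-OFF) define Family I, A2→A1 defines Family II, identical
  attractors on both sides are unclassified (the border then forms along
  a manifold without a basin-to-basin transition).
* **Solution class** I/II/III is a rule on the anterior (35–50%EL)
  Kr/gt pattern at τ with a 128-unit half-max: class I has both the
  anterior *gt* domain and an anterior *Kr* border, class III has
  neither (with Kr low), class II is the remainder (typically ectopic
  anterior Kr in place of gt). The thresholds and window are documented
  conventions operationalising a verbal description.
* **Response curves** plot, per profile, the Bcd concentration at x*
  against x*, where x* is either the initial-Hb/boundary intersection or
  the border position; the mass variant integrates the Bcd and Hb
  patterns over 35–64%EL (trapezoid at 0.1%EL). The knockout control
  zeroes the *hb* row of T (all four gap inputs to *hb*, keeping Bcd,
  Cad and Tll), which removes the network reaction and linearises the
  response.

## Canalization statistics

Positional summaries report the full range (max − min) and the sample
standard deviation (n−1 denominator; the estimator convention is the
package's, as the source does not state one), stratified as three
position kinds (intersections, *hb* borders, Bcd thresholds) × (Family
I, Family II, full set); strata with fewer than two members are marked
absent. The filtration rate is 1 − sd_out/sd_in. At coarse lattices the
border–intersection correlation has a step-like form (discrete nuclei,
no diffusion in the shorted model); tests use the continuous
interpolation mode.

## Synthetic data: what it emulates and what it does not

All inputs are generated programmatically:

* **Bcd ensembles** — lognormal A and l (positivity), median amplitude
  200 units, decay length 15%EL. Presets: *wide* (A_cv = 0.3,
  l_cv = 0.05), emulating a basic-normalized ensemble with exaggerated
  amplitude variance, and *narrow* (A_cv = 0.08, l_cv = 0.002), built so
  the threshold-position sd ≈ √((A_cv/l̄)² + (x_ref·l_cv)²) ≈ 1.2%EL,
  the scale reported for variance-minimized ensembles. The real (A, l)
  joint distribution is not reproduced — these are qualitative
  emulations, and per-profile counts of mechanisms/families from real
  ensembles are explicitly not reproduction targets.
* **Raw profiles** — s_j·A_j e^{−l_j x} + q(x) + Gaussian noise, with
  lognormal staining scales (cv 0.2) and default quadratic background
  (20, 0.1, −0.001); the generating parameters are returned for recovery
  tests.
* **Maternal Hb** — a decreasing logistic bounded by Ω's 100, midpoint
  47%EL, steepness 4%EL.
* **Cad/Tll tables** — Cad rises posteriorly (logistic, midpoint 60%EL)
  and ramps up in time to its T6 profile; Tll is confined posterior of
  70%EL and exactly zero in the analysis window. Both freeze at T6.
* **Circuit fixtures** — `bistable_border` is a mutually repressing
  hb/Kr pair (T = ±0.05) with hb autoactivation, Bcd activating hb
  (m = 0.05) and Cad weakly activating the posterior genes; across the
  window it carries exactly the attractor pair A1 = 1000 and A3 = 0100
  whose protocol basin boundary rises from ≈40 to ≈57 Hb units between
  37 and 57%EL and crosses the default maternal Hb gradient near
  47%EL. `monostable` and `decoupled` (closed-form equilibria
  R g(h)/λ) support degenerate-case tests. Fixture phase-portrait
  claims are re-verified in the test suite, never trusted.
* **Toys** — `1d_bistable` (auto-activating single gene; separatrix =
  middle root of the scalar fixed-point equation, found by bracketed
  root finding on the closed form), `2d_saddle` (symmetric mutual
  repression; saddle on the diagonal with eigenvalues −λ ± |R g′ T| and
  unstable eigenvector (1,−1)/√2), and `1gene_fold` (Bcd-driven fold
  with the closed-form tangency locus R g′(u*) T = λ).

The synthetic conditions deliberately omit several features of real
data: nuclear-level measurement noise, non-exponential Bcd tails,
spatially varying backgrounds, correlated (A, l) variation, and
parameters fitted to expression patterns. Passing tests therefore
demonstrate the correctness of the machinery and the geometric
mechanism of canalization (a basin boundary sloping against the
maternal gradient compresses crossing-position spread), not the
quantitative variance figures of any real ensemble.

## Problem sizes and determinism

Default analyses run at desk scale: 11 cycle-13 nuclei in the window,
50-embryo ensembles, 100 Monte-Carlo samples per nucleus plus bisection
sharpening (the partition API defaults to 10 000 samples for standalone
use), 21×20 plane scans. Every random draw derives from an explicit
seed; reruns with the same configuration are bitwise identical.

## Known limitations

* The per-nucleus label matching of the plane scan can mislabel across a
  grid cell containing several bifurcations; refine the grid near
  suspicious boundaries.
* Basins of limit cycles and basins over the full 4-D cube are out of
  scope (initial conditions are restricted to Ω by design).
* The pipeline classifies solution classes on the shorted solutions by
  default for speed; the class II definition is diffusion-sensitive, so
  full-model classification should be used when that distinction
  matters.
* Parameter fitting (simulated annealing), 3-D embryo geometry, and
  image quantification are out of scope.
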
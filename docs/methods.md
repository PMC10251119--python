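# Methods

## The model

`driftbalance` simulates founder lineages of identical heterotrophic
bacteria competing on a substratum under low-nutrient conditions, and
measures how large a deterministic growth advantage must be before it
reliably overcomes ecological drift.

**Geometry.** Spherical cells live in a cuboid domain, periodic in X and Y,
bounded below by a hard substratum (z = 0) and above by a bulk-liquid
boundary at a fixed height. `sqrt(N)` x `sqrt(N)` founders start on an
evenly spaced grid at the base; the X/Y edge equals
`sqrt(N) * spacing * initial_diameter`, so under the periodic wrap every
founder has identical surroundings. That symmetry is what makes the
drift-fairness test meaningful: no site is geometrically privileged.

**Growth.** Each cell grows at the Monod rate
`mu = mu_max * S / (K_s + S)` evaluated at the substrate concentration of
its voxel, and its mass follows the exact exponential update
`m <- m * exp(mu * dt)`. Mass and diameter are tied by a constant-density
sphere convention `m = rho * pi * d^3 / 6`.

**Division.** When a cell's diameter exceeds 1.36 um it divides. The first
daughter receives a uniform U(40%, 60%) share of the biomass, the second
the exact remainder; the daughters are placed tangent along a direction
drawn uniformly on the unit sphere, centred on the parent. These two draws
are the *only* randomness in the model; they come from a single Park-Miller
minimal-standard stream per run (a = 16807, m = 2^31 - 1), consumed in a
fixed order (split fraction, then cos-theta, then azimuth). Directions use
inverse-transform sampling rather than rejection so the number of draws per
division never varies and seed streams are portable. A run is therefore a
pure function of `(config, seed)`, and re-running with the same seed
replays the identical sequence of "luck" — the experimental handle the
whole pipeline is built on.

**Mechanical relaxation.** After growth and division, overlapping spheres
are pushed apart along their centre lines (half of the damped overlap
each), with minimum-image wrapping in X/Y and centres clamped above the
substratum. Pairs are found with a deterministic cell-list search and
relaxed by Gauss-Seidel sweeps (immediate updates in a fixed pair order),
until the largest overlap, relative to the pair's radius sum, falls below
`relax_tol` on a freshly rebuilt neighbour list. There are no explicit
spring/dashpot constants: the overlap projection reproduces the "shoving
into empty space" behaviour without contact-mechanics calibration.

**Substrate.** A single generic nutrient diffuses from the fixed-value top
boundary and is consumed where cells sit (oxygen is treated as
non-limiting, and there is no imposed flow, so advection is omitted).
Because diffusion at micrometre scales relaxes orders of magnitude faster
than growth, the field is solved to steady state before every growth step
(quasi-static transport) rather than integrated in time:

    D * laplacian(S) = sum over cells of  m * (exp(mu*dt) - 1) / (yield * dt)

apportioned to each cell's voxel. The `(exp(mu*dt)-1)` factor makes the
reaction term's integrated consumption equal the biomass gained over the
step divided by the yield, so the growth/uptake ledger closes exactly (the
test suite checks it to 1%, it holds to ~1e-6).

**Stopping.** A run ends when total cell volume reaches
`stop_volume_fraction` of the full cuboid. Final per-lineage biomass
fractions `X_i / X_t` are compared with the neutral expectation
`X_E = X_t / N` and classified as languishing (`X_i < 0.3 X_E`), thriving
(`X_i > 0.9 X_E`) or barely surviving (the closed interval between). The
"biggest loser" is the lineage with the minimum fraction (ties, which have
probability zero in floating point, break to the lowest lineage id).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `mu_max` | 1.0 | 1/h | baseline maximum specific growth rate |
| `K_s` | 3.5e-5 | kg m^-3 | half-saturation constant |
| `yield` | 0.61 | kg/kg | biomass per substrate consumed |
| `initial_diameter` | 1.0e-6 | m | founder size |
| `division_diameter` | 1.36e-6 | m | division threshold |
| `bulk_concentration` | 1.0e-4 | kg m^-3 | top boundary and initial field |
| `domain_height` | 2.0e-4 | m | fixed even when X/Y shrink |
| `stop_volume_fraction` | 0.20 | — | biomass volume fraction at stop |
| `density` | 150 | kg m^-3 | mass<->diameter convention, see below |
| `diffusivity` | 3.6e-6 | m^2/h | 1e-9 m^2/s, a small solute in water |
| `voxel_edge` | 5.0e-6 | m | horizontal substrate voxel edge |
| `voxel_edge_z` | 2.0e-6 | m | vertical edge, see below |
| `mu_dt_max` | 0.1 | — | per-step relative mass change cap |
| `relax_tol` | 1.0e-3 | — | overlap tolerance (fraction of radius sum) |

The biomass density is a convention, not a physical claim, but it is *not*
a free dial on its own: uptake scales with mass, so changing the density
alone changes how strongly the biofilm depletes the field. The true
invariance is a joint scaling — density, bulk concentration and `K_s`
multiplied by one factor leave every dimensionless outcome unchanged (the
Monod ratio and the per-concentration sink are both homogeneous of degree
zero). With a power-of-two factor the symmetry is bit-exact in floating
point, and the test suite asserts exactly that.

The vertical voxel edge deserves its own paragraph. Drift in this model is
mediated entirely by substrate access: a lineage wins because random
division directions and splits happen to stack its cells where
concentrations are higher. If the voxel grid cannot resolve the vertical
gradient across the young biofilm (which is a few cell diameters tall when
fates are decided), every cell sees the same concentration, lineage
fractions remain exactly `1/N` forever, and drift never materialises — we
verified this happens with 5 um and coarser vertical voxels. The default
is therefore anisotropic: 2 um vertically (finer than a division-sized
cell), 5 um horizontally (the vertical gradient dominates; horizontal
differentiation adds second-order shading effects).

## Numerical choices

* **Growth integration** uses per-cell exponential updates with the step
  adapted so the fastest-growing cell changes mass by at most `mu_dt_max`
  (10%). Divisions are checked after every update; a daughter can never
  re-cross the threshold within the same step (0.6 x 1.105 < 1).
* **Substrate solver.** The Monod sink is linearised semi-implicitly
  (`rate = coeff(S_old) * S`), which keeps the discrete operator an
  M-matrix, so every Picard iterate is nonnegative and bounded by the bulk
  value; iteration stops when the field changes by less than 1e-6 of the
  bulk. Above the highest cell the steady state is exactly linear in z,
  so the grid is truncated a few layers above the biomass and the top
  truncated layer coupled to the bulk value through a single implicit
  conductance (`cz / remaining_layers`). For the discrete operator this is
  exact, not an approximation, and it cuts the solve cost by roughly the
  ratio of domain height to biofilm height.
* **Relaxation order.** Gauss-Seidel with a fixed pair enumeration is
  deterministic and converges faster than Jacobi sweeps; damping 0.8
  avoids overshoot in dense packings. Coincident centres (measure-zero)
  fall back to a fixed displacement axis.
* **Logistic fits** minimise squared error on the probability scale, as
  the sigmoid-profile fitting is described; profiles whose observed range
  is below 0.1 are declared degenerate (mu50 unidentifiable) and returned
  as non-converged fits rather than raising. `mu50` outside the swept
  range is flagged as extrapolated. A binomial-GLM route is available via
  `statsmodels` for users who want likelihood-based uncertainty, but the
  least-squares fit is the canonical path.
* **Spread widths** come from inverting the fitted curve in closed form:
  `spread95 = 2 ln(39) / |k|`, `spread68 = 2 ln(5.25) / |k|`. Their ratio,
  `ln 39 / ln 5.25 ~ 2.209`, is parameter-free — a useful internal check.
* **Bootstrap intervals for (k, mu50)** are parametric (binomial redraws
  from the fitted profile). A calibration study at truth (-0.2, 15), 120
  trials/point, found the bootstrap standard errors accurate but the
  percentile, basic and BCa intervals all undercover the steepness
  parameter (0.89-0.92 at nominal 95%), whose bootstrap distribution is
  skewed. The default interval is therefore the normal-approximation
  bootstrap interval with Student-t critical values at
  `n_points - 2` degrees of freedom; joint statements about both
  parameters use Bonferroni-adjusted levels. Measured joint coverage of
  the simultaneous 95% construction is 0.98 across seeds.
* **GAM machinery.** Penalized regression splines built in-package:
  P-spline bases (uniform extended knots, so the second-order difference
  penalty's null space is exactly the linear functions), sum-to-zero
  constrained marginals, ti()-style tensor products for interactions, one
  smoothing parameter per term chosen by GCV with cyclic golden-section
  search. When GCV cannot distinguish (ties within 1e-6 relative), the
  smoother model wins — on exactly linear data every term then shrinks to
  effective df 1. Few-level variables (population, spacing: 3 levels) get
  polynomial bases of maximal identifiable degree with curvature-only
  penalties. Term p-values are Wald-type tests on the Bayesian posterior
  covariance of the penalized coefficients at the term's effective df —
  the standard approximation for penalized splines, adequate for the
  backward-selection ordering they drive. An independent cross-check
  against R's `mgcv` on a smooth two-factor surface is part of the test
  suite.
* **Backward selection** drops the least significant term among the
  highest-order non-significant (p > 0.05) terms, refits, and repeats; a
  term nested inside a retained significant interaction is protected — in
  particular main effects stay whenever one of their interactions is
  significant.
* **MLR response.** The eps-guarded logit `log(p/(1-p+eps) + eps)` with
  `eps = 1e-6`, inverted exactly (not via the plain logistic) before
  predictions are clipped to [0, 1] and the probability-scale RMSE is
  computed, so MLR and GAM errors are commensurable. The GAM is Gaussian
  on the probability scale and its predictions are deliberately left
  unclipped, with a flag recording excursions outside [0, 1].

## The synthetic-data generator

Two generators serve the pipeline:

1. **The simulator itself** is the data source for everything upstream of
   the probability maps. Its defaults are the study conditions (founder
   counts 4/9/16, spacings 2.5/5/10 diameters, kinetic grid -50..+50% in
   steps of 10, 20% stop fraction, seed panels reused across combinations).
2. **`generate_fixture_pmap`** synthesises p_thrive surfaces directly from
   the logistic threshold model — binomial draws at `n_seeds` trials per
   grid point around `p = 1/(1 + exp(-k (mu50(dKs) - dmu)))`, with
   `(k, mu50)` optionally varying by crowding condition. It exists so the
   fitting and modelling stages can be tested and calibrated against known
   truth without cluster-scale simulation.

What the fixture does *not* emulate: the paired-seed correlation structure
between grid points (each point is drawn independently, whereas real
re-runs share baselines across the kinetic grid), deviations of true
response profiles from an exact logistic, and any spatial mechanism at
all. Passing fixture-based tests therefore demonstrates that the
*statistical machinery* is correct and calibrated — not that the simulator
produces logistic profiles; that link is made separately by the
scaled-down sweeps in `analysis/`.

## Desk-scale problem sizes

The full campaign behind a study-grade probability map (1089 combinations
x 120 seeds) is a cluster-scale computation. The analyses and tests here
run the identical protocol at deliberately reduced sizes, chosen as the
package's own desk-scale conditions:

* drift-neutrality checks: 60 seeds of the 4-founder / 5-diameter design
  and 30 seeds of the 9-founder / 10-diameter design, stopped at 5%
  biomass volume fraction. Stopping earlier preserves the symmetry
  argument exactly (no site is privileged at any stop point), and lineage
  fates are largely set early in growth.
* the kinetic sweep: 9 founders, 10-diameter spacing, the unchanged-K_s
  line of the kinetic grid, 20 seeds, 5% stop.
* fitting-stage calibrations: fixture surfaces at 120 seeds/point, the
  study's seed-panel size.

Quantities that depend on the absolute scale (the exact mu50, spread
widths) are reported from these runs as scaled-down observations, not as
reproductions of cluster-scale values.

## Known limitations

* Contact mechanics are reduced to overlap projection: no adhesion,
  friction, or fluid coupling, so colony morphologies are smoother than a
  full mechanical model would give. The drift/selection statistics, not
  morphology, are the fidelity target.
* Individual run outcomes are chaotic: any change to numerics (voxel size,
  relaxation order, floating-point environment) reshuffles which lineage
  wins for a given seed. Only distributional statements — fairness of
  loser sites, p_thrive surfaces, fitted balance parameters — are stable,
  and only those are asserted.
* Oxygen, EPS, multiple species, detachment and cell death are out of
  scope; the substrate is a single generic nutrient.
* The Wald-type smooth-term tests and the GCV search are approximations;
  model selection conclusions are robust to them in the regimes tested,
  but exact p-values should not be over-read.
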
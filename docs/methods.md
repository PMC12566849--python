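# Methods

`nanomill` models the evolution of a drug nanosuspension's particle size
distribution (PSD) during wet media milling, where two mechanisms compete:
breakage of particles by bead collisions and agglomeration of the
fragments. It implements a discretized population balance simulator, an
evolutionary estimator of the kernel parameters from laser-diffraction PSD
time series, an nth-order comminution kinetics model for the median size
D50(t), and the scalar hydroxyl-radical scavenging statistic used to track
the biological activity of the milled product.

## Population balance model

The number density n(v; t) over particle volume v obeys

    dn/dt = (1/2) ∫₀ᵛ β(v−ε, ε) n(v−ε) n(ε) dε  −  n(v) ∫₀^∞ β(v, ε) n(ε) dε
          + ∫_v^∞ a(ε) b(v|ε) n(ε) dε  −  a(v) n(v)

with

* breakage rate `a(v) = K1 · v^μ` (power law; μ = 0 is size-independent
  breakage, μ = 1 makes large particles break proportionally faster);
* agglomeration rate `β(v1, v2) = K2 · (v1^y1 + v2^y2)(v1^−y1 + v2^−y2)`,
  the generalized diffusion-limited (Brownian) coagulation kernel. The
  power factors y1, y2 are the kernel exponents: y = 1/3 recovers the
  classical Brownian form exactly, and y → 0 degenerates to the constant
  kernel. Fitted values for this system lie in 0.01–0.28, i.e. between
  those two classical limits. (An exponent of 1/y with y values in that
  range would make the cross terms (v1/v2)^(1/y) of order e^100 across the
  occupied size range and the equations unintegrable, so that reading is
  rejected.)
* daughter distribution `b(v|ε) = θ(v/ε)/ε`, where the self-similar shape

      θ(ξ) = p · ξ^c (1−ξ)^(c+(c+1)(p−2)) · Γ((c+1)p) / (Γ(c+1) Γ((c+1)(p−1)))

  is p times a Beta(c+1, (c+1)(p−1)) density. The normalization is exact:
  the number integral over (0,1) is the mean daughter count p and the mass
  integral is 1, both by the beta-function identity. The shape parameter c
  classifies the breakage regime — c < 0: abrasion/erosion (fine debris
  dominates, θ diverges at ξ→0); c = 0 with p = 2: uniform binary
  breakage (θ ≡ 2); c > 1: an interior fragment-size mode, the signature
  of efficient uniform milling.

### Units and normalization

Diameters are sphere-equivalent (laser diffraction's convention),
v = (π/6) d³. Internally all volumes are divided by the volume of a
reference diameter `d_ref` — by default the volume-weighted mean diameter
of the initial PSD — so typical dimensionless volumes are near 1 and the
kernel powers stay tame. States are scaled so the total particle volume
fraction Σ xᵢNᵢ is 1 at t = 0. The absolute number-concentration scale of
the suspension is not identifiable from volume-percent curves, so K2 (the
only parameter multiplying N²) absorbs it; K1 and K2 are therefore rate
constants on this normalized scale, per minute. Time is minutes
throughout; file boundaries use μm for PSD bin edges and nm for D50.

### Discretization

The grid is geometric in volume with ratio r = 2^(1/q) (`q` bins per
volume doubling, so one diameter doubling spans 3q bins); pivots sit at
geometric bin centers. Production default: q = 3 over 10 nm–100 μm
(120 bins). Inverse problems use q = 1 over 0.1–100 μm (30 bins), trading
resolution for speed; the grid-refinement check below shows the final D50
moves < 2% between q = 3 and q = 6, and estimation compares simulated and
observed curves on the *same* grid, so coarse-grid bias largely cancels.

Discrete events are assigned by the fixed-pivot rule: a birth of volume s
between pivots xᵢ and xᵢ₊₁ is split with weights ((xᵢ₊₁−s) and (s−xᵢ))/
(xᵢ₊₁−xᵢ), conserving both number and mass per event.

* **Agglomeration.** Birth = ½ Σⱼₖ over ordered pairs of β̃ⱼₖ NⱼNₖ assigned
  to the pivots bracketing xⱼ+xₖ; death = Nᵢ Σⱼ β̃ᵢⱼNⱼ, with
  β̃ = (β(v1,v2)+β(v2,v1))/2. When y1 ≠ y2 the printed kernel is
  order-dependent; the ordered double sum makes β̃ the effective pair rate,
  and using the same β̃ in the death term makes birth and death mass
  balance exactly (with raw β they do not). An explicit `symmetrize` flag
  on the kernel itself is also available, default off. Aggregates beyond
  the top pivot are lumped into the top bin with number s/x_M (mass
  conserving).
* **Breakage.** The fragment matrix b_{i|j} integrates θ in closed form
  (regularized incomplete beta functions) over each inter-pivot interval
  of the parent xⱼ and splits each interval's number and mass between the
  bounding pivots. Fragment mass below the smallest pivot is lumped into
  bin 1 with its count adjusted to conserve mass; consequently column mass
  sums satisfy Σᵢ xᵢ b_{i|j} = xⱼ to machine precision, while column
  number sums equal p only up to the (normally negligible) sub-pivot
  correction. The smallest bin does not break (a₁ = 0): no sub-grid sink.

### Time integration

A variable-step, variable-order backward differentiation formula
(`scipy.solve_ivp` BDF) with analytic Jacobian, rtol 1e-6 and atol 1e-10
on the normalized scale. Integrator excursions below zero smaller than
1e-8 of the state maximum are clipped; anything larger is an error. Total
particle volume is monitored at every output time; relative drift beyond
1e-3 aborts (observed drift in tests is ≲1e-12). Dense kernel tables keep
right-hand-side cost at two small matrix products; grids beyond 512 bins
are rejected rather than silently thrashing memory.

## Parameter estimation

The inverse problem minimizes the sum over observation times (after t = 0)
and instrument bins of squared volume-percent differences between
simulated and observed curves. The t = 0 curve is the initial condition of
the initial-value problem, not a fitted quantity. Full curves rather than
D50 alone are compared because the data being emulated are full
distribution curves. The optimizer is differential evolution (rand/1/bin,
F = 0.7, CR = 0.9), seeded, single-threaded and with immediate updating,
so a fit is bit-reproducible given its seed. K1 and K2 are searched in
log10 space (their plausible ranges span decades); μ, y1, y2, c, p
linearly. A candidate whose forward simulation fails receives a finite
penalty of 1e9 so one pathological corner of parameter space cannot abort
a fit. Any subset of parameters may be frozen via the fixed-parameter
mask.

## Comminution kinetics

The median size decays as

    D50(t) = Dlim + [(D50(0) − Dlim)^(1−n) + (n−1) k t]^(1/(1−n))

with grinding limit Dlim (nm), rate constant k (nm^(1−n) min⁻¹) and order
n > 1. Fitting minimizes squared residuals of log D50 (the size spans two
decades; log residuals weight the whole trajectory evenly) by damped least
squares with Dlim constrained below the smallest observation, plus up to 5
deterministically perturbed restarts. D50(0) is taken from the t = 0 datum
when present, otherwise supplied by the caller. R² and SSR are reported on
both the log scale (the fitted scale) and the linear scale, because which
scale a published SSR refers to is not always recoverable. Identifiability:
on log-log axes D50(t) − Dlim has asymptotic slope −1/(n−1), and the
late-time plateau pins Dlim; recovery from noiseless curves is exact to
≲1e-10 relative, and under 2% multiplicative noise the median recovered
Dlim over 20 replicates stays within 5%.

## Scavenging assay

E% = (A0 − Ax)/A0 × 100 for blank absorbance A0 and sample absorbance Ax.
Exact arithmetic, rounded to two decimals only at the reporting boundary;
E% is scale-invariant in the absorbances and strictly decreasing in Ax.
Negative values (Ax > A0, pro-oxidant readings) are physically meaningful
and produce a warning, not an error. The summary table adds each sample's
ratio to the first (reference) sample.

## Synthetic data

The generator stands in for unreleased raw instrument exports.

* **Initial PSD**: a two-mode lognormal volume-weighted diameter mixture —
  raw suspensions are bimodal at the start of milling. Defaults: mode 1
  median 1.5 μm (gsd 1.6, weight 0.35), mode 2 median 19 μm (gsd 1.5,
  weight 0.65), placing the analytic D50 at ≈14.1 μm to match the measured
  starting median of 14.2 μm. The curve is the analytic mixture CDF
  differenced across grid edges (no sampling noise).
* **PSD series**: the package's own simulator run forward from that curve,
  then multiplicative lognormal noise on the volume percents (default sd
  2%, the order of laser-diffraction repeatability), renormalized to 100%.
  Noise 0 reproduces the simulator bit-exactly.
* **D50 series**: the kinetics law at 25 log-spaced times in [1e-3, 60]
  min (log spacing because the fitted parameter sets imply a fast early
  transient), with the same noise model.
* **Absorbances**: the measured blank/sample values by default.

All generators are bit-deterministic under a fixed seed. Because the PSD
series is generated by the same forward model that estimation inverts,
recovery tests demonstrate the estimator's correctness and identifiability
— not robustness to model misspecification, instrument smearing (Mie
optics, obscuration), or real repeatability structure, none of which are
emulated.

## Numerical choices and degenerate inputs

* Kernel powers are evaluated as exp(e·log v) with a hard overflow guard
  at |e·log v| > 700; overflow raises rather than saturates, because
  saturation silently corrupts fits (during estimation the failure is
  converted to the finite penalty).
* Daughter-distribution integrals use closed-form incomplete-beta
  expressions in the solver and adaptive quadrature (tolerance 1e-6) in
  verification.
* Rebinning between instrument bins and grid bins allocates volume
  proportionally to interval overlap in log diameter: deterministic and
  mass-conserving; percentile diameters interpolate cumulative volume
  linearly against log10 diameter.
* Empty distributions, all-zero states, non-ascending edges and
  volume-percent sums off 100 by more than 0.1 are rejected with specific
  errors; CSV/YAML readers reject unknown or missing keys and report line
  numbers.
* Zero-rate parameter sets (K1 = K2 = 0) freeze the state exactly; a
  simulation asked only for the initial time returns it without
  integrating.

## Known limitations

* The absolute number-concentration scale is not identifiable from
  volume-percent data; K2 values are meaningful only relative to the
  normalization above.
* With the fitted parameter sets and this normalization, agglomeration
  and breakage balance quickly (the synthetic curves are near stationary
  after ~10 min); the estimator's identifiability then rests mostly on
  the shape of that balance, which the K1-recovery tests probe directly.
* The coarse 30-bin estimation grid under-resolves narrow modes; fits on
  real exported curves should use q ≥ 3 and the instrument's native
  binning.
* No growth/nucleation terms, no spatial inhomogeneity, no bead-motion
  mechanics, and no link from (Dlim, k, n) to the kernel parameters beyond
  the qualitative parallel between k and K1.
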
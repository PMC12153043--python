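# Methods

This note records the models implemented in `diatomgel`, the assumptions
behind them, the defaults and where they come from, and the numerical
choices that matter when reproducing results.

## Indentation rheology

A rigid sphere of radius R (default 1.565 mm, i.e. a 3.13 mm-diameter
indenter) is driven at constant rate (default 0.01 mm/s) into a gel
half-space to depth d_max (default 1 mm) and held (default 3600 s).

* **Loading.** Hertz contact for a rigid sphere on an elastic half-space,
  F = (4/3) E\* √R d^{3/2}. E\* is reported directly as the *effective*
  modulus with no Poisson-ratio factor separated out; any fixed elastic
  prefactor convention is absorbed into E\*. The fit is least squares of F
  on d^{3/2} through the origin over the loading ramp (≥ 10 samples
  required). Units at the interface are N, mm, kPa; with those units
  Hertz's law carries a factor 10⁻³.
* **Relaxation.** The hold segment is fitted with
  F(t) = F∞ + F₁ e^{−t/τ₁} + F₂ e^{−t/τ₂}, an empirical stand-in for the
  gel's viscoelastic/poroelastic response; no constitutive poroelastic
  model is attempted. Time is re-zeroed at the start of the hold and the
  first 1 s is discarded to avoid ramp-stop transients (amplitudes remain
  referenced to the hold start). The nonlinear fit is multi-started on a
  4 × 4 log-spaced (τ₁, τ₂) grid over [10, 10⁴] s, only ordered pairs
  tried, amplitudes bounded non-negative; the lowest-RSS solution is kept
  and reported with τ₁ < τ₂. If every start fails a convergence error is
  raised rather than returning a bad fit.
* **Residual modulus.** E\*∞ = 3 F∞ / (4 √R d_max^{3/2}), the inverse Hertz
  relation at the hold depth.
* **Concentration scaling.** E = a φ^b by OLS of log E on log φ
  (statsmodels), with the standard error of b from OLS theory. Measured
  agarose gels give b in the 1.5–2.2 range; the synthetic default is 1.9.

## PTV strain mapping

* **Detection.** Local maxima (`skimage.feature.peak_local_max`, minimum
  separation default 5 px, threshold relative to the frame's dynamic range)
  refined by an intensity-weighted centroid of the background-subtracted
  patch in a (2·min_separation+1)² window; refined detections closer than
  the minimum separation are merged keeping the brighter. On isolated
  noiseless spots the centroid is accurate to ~0.01 px; accuracy degrades
  when point-spread functions overlap, which in practice caps useful bead
  densities near 0.01 beads/μm² at the default optics (sd 1.2 px spots on
  a 0.98 μm/px grid).
* **Linking.** Frame-to-frame assignment minimizing total squared
  displacement under a hard gate (no link longer than `max_disp`),
  solved exactly with the Hungarian algorithm on each connected component
  of the gated candidate graph; dummy nodes price "no match" at the gate
  cost, so tracks start and terminate naturally. No gap closing. A greedy
  nearest-neighbour mode exists as a fallback for very dense data.
* **Expansion time course.** Tracks spanning the first and last frame are
  ranked by total displacement; the top 5 % are kept (ties broken by track
  id), each normalized by its own start-to-end total, and averaged per
  frame. A degenerate (no-motion) case returns zeros, not NaN.
* **Radial profile.** Distance is |x − cell centre| − h₀/2, clamped at
  zero, so a particle at the cell wall sits at distance 0.
* **Strain maps.** At each node of a regular grid (default spacing 10 μm)
  the displacement field is regressed on a local polynomial over particles
  within `window_radius` (default 25 μm) with Gaussian weights (sd =
  window_radius/2 by default). The deformation gradient A is the linear
  term; ε = ½(A + Aᵀ). The default basis is *quadratic* (`poly_order=2`):
  the quadratic terms absorb field curvature, which otherwise biases the
  affine gradient by up to a few 10⁻² strain near a strongly curved field
  sampled at uneven bead positions; with them the error against the
  closed-form cavity field drops to below 1 % strain at 30 μm from the
  wall. `poly_order=1` recovers the plain affine fit. Exactly affine
  fields (including pure infinitesimal rotations, which give ε = 0) are
  reproduced to machine precision by both. Nodes with fewer than
  `min_support` neighbours (default 6, never below the basis size) or a
  rank-deficient/ill-conditioned neighbourhood are flagged invalid, never
  extrapolated. Nodes within one window radius of the data boundary have
  one-sided neighbourhoods and should be interpreted with care; the
  validation excludes them. Wall strains of order 20–30 % strain the
  small-strain assumption itself; a Green–Lagrange option
  (`strain="green"`) is provided. View alignment with the cell's expansion
  plane is a user-supplied in-plane rotation (`rotate_coordinates`);
  automatic orientation detection is out of scope.

## Growth model

* **Cavitation criterion.** P_c = c · E\*∞(φ) with c = 1 by default (the
  theory fixes c only to order unity; it is exposed as
  `cavitation_prefactor`). Division requires P > P_c strictly; equality
  (within rounding) does not open the gel. The default residual-modulus
  law E\*∞ = 1.511 φ^{1.9} kPa is *calibrated, not transcribed*: the
  exponent is set to 1.9 and the prefactor chosen so that E\*∞(10 %) =
  120 kPa, the stiffness at which division ceases and hence the inferred
  median turgor pressure.
* **Two-regime laws.** Division time: 7.5 h plateau for φ ≤ 2 %, then the
  line through (2 %, 8 h) and (7 %, 20 h); both printed values are honored,
  which leaves a small jump at the breakpoint (plateau 7.5 h, rising branch
  anchored at 8 h). No division at φ ≥ 10 %. Relative expansion: 0.39
  plateau (midpoint of the reported 40–38 % range), then the line through
  (2 %, 0.37) and (7 %, 0.09), clamped at zero and forced to zero at
  φ ≥ 10 % (the linear extrapolation alone would cross zero near 8.6 %).
  Viability: cumulative fractions reaching the three transitions,
  piecewise-linear in φ through the anchors (1 %, (0.89, 0.44, 0.29)),
  (7 %, (0.25, 0, 0)), (10 %, (0, 0, 0)), flat below 1 %. The cumulative
  (not conditional) reading of the fractions is adopted; conditional
  values are derivable as ratios.
* **Habitat conversions.** Hydrostatic gradient 10 kPa/m; diffusion
  timescale L²/D with unit-safe output.

## Synthetic data

The generators emulate the statistical and mechanical structure the
analysis assumes — not the microscope. Deliberate simplifications: 2D
Gaussian point-spread (sd 1.2 px) on a 16-bit grid with optional Gaussian
read noise, no z-structure, no autofluorescence background, no bleaching or
drift; force noise additive and white; the displacement ground truth is the
incompressible expanding-sphere field (chosen for its closed-form strain
oracle), optionally anisotropic variants are out of scope of validation.
Passing tests therefore demonstrate correctness of the *algorithms* against
known ground truth at realistic noise levels, not robustness to every
artifact of real confocal data (uneven illumination, out-of-focus beads,
cell autofluorescence bleeding into the tracer channel).

Defaults that set the study conditions: confocal geometry 512 × 512 px over
500 μm; frame interval 3 min; founder cell sizes uniform on 111–139 μm;
relaxation truth τ₁ = 99 s, τ₂ = 1644 s with equal amplitudes (F₁ = F₂,
amplitudes are not otherwise constrained and the equal split keeps both
exponentials identifiable); 1 % relative force noise.

Single-cell events: per-transition Bernoulli survival with the conditional
probabilities implied by the cumulative viability law; transition durations
lognormal (shape 0.25) about division_time(φ) times per-transition
multipliers (1.0, 0.7, 1.0), chosen so the cumulative schedule at 1 % agar
(~7.5, 12.8, 20.3 h) matches the observed ~8/13/21 h sequence; expansion
normal (sd 0.05) about expansion_fraction(φ), clamped non-negative.

Colony series: a Yule birth process with exponential per-cell division
intervals of mean division_time(φ) (memoryless intervals make the
construction exact and vectorizable), saturating at a carrying capacity
drawn lognormal about N̄(φ) (anchors 18 cells at 0.5 %, 6 at 3.5 %) with
shape σ(φ) rising 0.30 → 1.00 over the same range — reproducing both the
10–20-cell histogram mode in soft gels and the 1–5-cell majority plus the
larger normalized variance in stiff gels. Whole-colony death is a constant
hazard λ(φ) calibrated from the day-21 survival anchors
(λ = −ln 0.80/21 d⁻¹ at 0.5 %, −ln 0.16/21 at 3.5 %, linear in φ, clamped
at zero); dead colonies freeze at their last size and count as dead from
the moment of the hazard event. While alive, the viable-cell count is
Binomial(n, 0.78) conditioned on ≥ 1 (a colony is alive exactly while at
least one cell fluoresces); the conditioning inflates the viable fraction
by ~0.01 when colonies are small. Colony size follows l/l₀ = n^{p(φ)} with
p interpolated between the calibrated endpoints (0.99 at 0.5 %, 0.59 at
3.5 %) and clamped to [⅓, 1] — chain-like to close-packed growth.

All randomness flows from one integer seed; each generator draws from a
fixed sub-stream (`default_rng([seed, offset])`), so outputs are
bit-reproducible and independent across generators.

## Validation problem sizes

The shipped validation exercises: indentation round trips noiseless and at
1 % noise × 20 seeds; exponent recovery over 50 series of 7 concentrations
× 3 replicates at 10 % lognormal scatter; a rendered 20–21-frame, 2000-bead
stack for the full PTV chain, with strain compared to the closed form on
interior nodes at least 30 μm from the cavity wall (relative to the field's
peak strain of 0.306 at the wall); and 10⁴ simulated colonies per
concentration for the day-21 statistics, where Monte-Carlo standard errors
are ~0.004 on the living fraction and ~0.06–0.18 cells on the mean count.

## Known limitations

* The Hertz prefactor convention means absolute moduli match measured
  values only up to a fixed multiplicative constant if a different
  convention was used upstream.
* No 3D tracking, no drift correction beyond optional global mean
  subtraction, no traction/stress inversion.
* The two-regime laws are calibrations of reported summary values, not
  mechanistic predictions; between anchors they interpolate linearly.
* The colony simulator's division-rate and capacity parameters reproduce
  day-21 cultivation statistics; intermediate-day trajectories are not
  calibrated and single colonies can reach capacity faster than real
  colonies grow.
* Oscillatory ("pulsating") cell displacements seen in very stiff gels are
  not modelled.
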
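# Methods

## Physical model

The sample is treated as a dilute continuous phase in equilibrium with
spherical condensed droplets of a single radius `R_drop`. Five parameters
describe it: the free diffusion coefficient in the dilute phase `D_dil`
(m²/s), the intrinsic diffusion coefficient inside the droplets `D_cond`
(m²/s), the condensed fraction of the observed species `ν_cond` (the dilute
fraction is always `1 − ν_cond`), the droplet radius `R_drop` (m), and the
interface permeability `p` (m/s). Exchange across the interface is
first-order with condensed→dilute rate `k_cd = 3p/R_drop` — permeability
times the surface-to-volume ratio of a sphere — and the reverse rate fixed
by detailed balance, `k_dc = ν_cond k_cd/(1 − ν_cond)`. The
population-weighted global rate `k_ex = ν_cond k_cd` and half-life
`t½ = ln2/k_ex` are the quantities most comparable to FRAP recovery rates.

Magnetization of the two pools under a gradient pair of wavevector
`q = γ g δ` obeys a pair of coupled linear (McConnell-type) equations with
decay rates `q²D_app` (condensed) and `q²D_dil` (dilute) plus the exchange
terms; the observed signal is the sum of the pools at `t = Δ`. The 2×2
system is solved in closed form through its eigenvalues (both real and
non-positive: the discriminant `(a₁₁−a₂₂)² + 4k_cd·k_dc` is a sum of
squares and products of non-negative rates).

### Restricted diffusion inside the droplets

The condensed pool's decay uses the classical narrow-pulse eigenmode
series for diffusion between reflecting boundaries a distance `R` apart,
truncated at `n_max = 2000` terms (configurable); terms whose exponent
`n²π²·D_cond·Δ/R²` exceeds ~745 underflow and are skipped. The series is
the *parallel-boundary* result applied with the sphere radius as the
boundary separation; the geometry is therefore an approximation of the
spherical pore, kept deliberately instead of a spherical-eigenmode
(Murday–Cotts/Neuman-type) series — the same length scale enters both, and
the parallel-boundary form keeps the model analytic and cheap. The
Monte-Carlo oracle used in the tests simulates the same 1-D reflecting
geometry, so oracle agreement validates the implementation of this series,
not the sphere-vs-slab geometric choice.

Numerical safeguards: at the diffraction condition `qR = nπ` the generic
term is 0/0 with removable singularity; whenever
`|(qR)² − (nπ)²| < 10⁻⁹ (nπ)²` the term's analytic limit
`exp(−n²π²D_condΔ/R²)/2` is used. The series value is clamped into
`[10⁻³⁰⁰, 1]` before any logarithm (every printed term is non-negative, so
the clamp is purely defensive against floating-point cancellation), and
`q = 0` returns exactly 1. The apparent coefficient `D_app = −ln E/b` uses
the analytic small-q limit at `b = 0` — the mean-squared displacement of
the confined walk over `2Δ`,
`(R²/Δ)(1/12 − 8 Σ_{n odd} exp(−n²π²τ)/(nπ)⁴)` with `τ = D_condΔ/R²` —
rather than evaluating 0/0.

`D_app` depends on `Δ`, yet it enters the exchange system as a constant
coefficient over `[0, Δ]`: each `(q, Δ)` point gets its own constant
matrix. This is an intentional model property (the apparent coefficient
summarizes the whole interval), not a numerical shortcut.

The 2×2 propagator uses `exp(At)v = e^{λ₂t}v + φ(A−λ₂I)v` with
`φ = (e^{λ₁t} − e^{λ₂t})/(λ₁−λ₂)`. For `(λ₁−λ₂)t > 10⁻⁴` the difference is
computed directly (both exponentials lie in [0,1], no overflow); below
that, a third-order Taylor expansion of `e^{λ₂t}(e^{z}−1)/(λ₁−λ₂)` covers
the near-degenerate and exactly degenerate (confluent) cases smoothly.

### b-value convention

`b = γ²g²δ²Δ` with no `Δ − δ/3` finite-pulse correction, matching the
narrow-pulse model. An `effective_diffusion_time` flag on the acquisition
scheme applies the correction for users fitting real bipolar-gradient
data; it is off by default and changes nothing for self-consistent
simulation + fitting.

## Binding (dispersed) variant

For a soluble complex in exchange with its free components the same
propagator applies with both pools isotropic: decay rates `q²D_complex`
and `q²D_free`, exchange rates `k_off` (complex→free) and the
pseudo-first-order `ν_complex k_off/(1 − ν_complex)` (free→complex). The
fitted bound fraction refers to a declared reference species (default: the
observed one); with known totals and stoichiometry it yields the
equilibrium concentrations, and `K_d = c₁_free·c₂_free/c_complex`,
`k_on = k_off/K_d`. The bound-fraction form of the mass-action quotient is
converted to molar concentrations before computing `K_d`, which is the
only dimensionally consistent reading.

## Fitting

All curves are fit jointly by minimizing the Euclidean residual norm `χ`.
The minimizer is Nelder–Mead simplex over transformed parameters — log for
`D_dil`, `D_cond`, `R_drop`, `p` (and `D_free`, `D_complex`, `k_off`),
logit for fractions — which enforces positivity and [0, 1] bounds without
constrained optimization. Because a single simplex start on the
5-parameter surface is not reliably global, `n_starts` (default 20) runs
are launched: the first from heuristic guesses (dilute coefficient from
the early-decay slope of the shortest-Δ curve, condensed fraction from its
large-gradient plateau, `R = 1 µm`, `p = 0.5 µm/s`, `D_cond = D_dil/100`),
the rest from seeded Gaussian perturbations in transformed space (scale
1.0). The loop stops early once a start reaches `χ < 10⁻¹⁰` — below
numerical noise, so for noiseless data that start is the global minimum.
Convergence tolerances default to `10⁻¹²` on the objective and `10⁻⁸` on
transformed parameters, 5000 iterations per start. Identical data + spec
(including the seed) reproduce bit-identical results.

Data are assumed normalized per curve; on ingest the reference is an
explicit `i0` column when present, otherwise the smallest-gradient point
of each curve. `fit_curve_scales=True` adds one free multiplicative scale
per curve instead, for data whose normalization reference is itself noisy.

Fewer than two distinct diffusion times is an error; fewer than six draws
a warning, since with sparse Δ coverage the droplet parameters degrade
sharply (the tests show the radius uncertainty more than doubling from six
curves to two).

### Uncertainties

At the optimum, the covariance of the transformed parameters is
`s²(JᵀJ)⁻¹` with `J` the central-difference Jacobian of the residuals
(relative step 10⁻⁵) and `s² = χ²/(N−P)` the residual variance — a
homoscedastic Gaussian noise model on normalized intensities. Standard
errors are mapped to natural scale by the delta method (`θ` for log
parameters, `ν(1−ν)` for logit). If the information matrix is singular
(condition beyond ~10¹²) the pseudo-inverse is used and parameters with
significant weight in the near-null space are flagged `unidentifiable` —
reported, never suppressed. This happens physically when the condensed
population is small (the condensed-phase coefficient is then essentially
unconstrained) or exchange is very fast.

## Synthetic data

`default_scheme` reproduces the standard acquisition: 16 gradient
amplitudes linearly spaced from 2% to 95% of a 0.535 T/m maximum, gradient
length 10 ms for protein (3.5 ms RNA, 2 ms water), and six diffusion times
{50, 100, 200, 350, 600, 1000} ms. Longitudinal relaxation limits Δ in
practice (~700 ms for folded domains, ~1 s for disordered proteins); pass
a custom Δ list for folded-domain work.

Noise is seeded additive Gaussian on normalized intensities, optionally
followed by renormalizing each curve to its smallest-gradient point as an
experimentalist would (`renormalize=True`, the default). That
renormalization makes the noise slightly correlated within a curve and
shifts fitted coefficients by a few percent at σ = 0.01 — a property of
the data processing, not of the estimator — so the uncertainty-calibration
study in the tests uses the pure additive model that the covariance
estimate assumes. The generator does not emulate droplet-size
polydispersity, T₁/T₂ relaxation weighting, finite-pulse gradient shapes,
or Rician magnitude noise; passing tests therefore validate the estimator
under the model's own assumptions, and real-data deviations from those
assumptions (above all size polydispersity) enter as model error, not as
noise.

## Validation oracles

Two brute-force oracles back the tests and never participate in fitting:

- a scaling-and-squaring matrix exponential (scipy) for the exchange
  propagator, checked to 10⁻¹⁰ absolute over 1000 random
  parameter/q/Δ draws;
- a Monte-Carlo random walk between reflecting boundaries with
  narrow-pulse encoding, `E(q) = ⟨cos q(x_Δ − x₀)⟩`, started from the
  uniform equilibrium distribution. Each Gaussian step is folded back into
  the domain by mirror reflection, which samples the reflected-Brownian
  transition density exactly at any step size; the step count therefore
  only enforces the configured RMS-step bound (≤ separation/50), and the
  only error is statistical. Agreement is required within 3 standard
  errors on a grid over qR ∈ [0.1, 4] at normalized times
  τ = D_condΔ/R² ∈ {0.01, 0.3, 2.0} with 10⁶/3×10⁵/5×10⁴ walkers — walker
  counts chosen so the whole grid runs in about a minute on one core,
  with the long-time limit additionally covered analytically by the
  motional-averaging plateau identity.

## Problem sizes and defaults

The reference computations use the full 16 × 6 acquisition grid
(96 points). The parameter-recovery runs use 20 multistart seeds; the
50-replicate noise study (σ = 0.01) uses 2 starts warm-started from the
generating values, since noisy optima lie near the truth and the study
measures estimator calibration, not global-search robustness. Kurtosis
diagnostics fit `ln(I/I₀) = −bD_app + (1/6)b²D_app²K` per curve by linear
least squares — the standard quadratic b-expansion; `K = 0` for Gaussian
diffusion, positive for mixtures and restricted motion.

## Known limitations

- Monodisperse spherical droplets only; heterogeneous size distributions
  bias the single fitted radius toward an average.
- The parallel-boundary series stands in for the spherical pore (above).
- Exchange outside roughly 1–100 s⁻¹ (relative to the accessible Δ range)
  leaves parameters weakly determined; the covariance flags this rather
  than failing.
- Populations below ~0.2 in either phase leave that phase's diffusion
  coefficient poorly determined.
- No relaxation weighting: pools are assumed to enter the diffusion block
  weighted by their populations alone.
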
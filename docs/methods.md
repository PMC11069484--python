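# Methods

## Model

The irreversible Michaelis–Menten mechanism is modelled by the planar
mass-action system for free substrate s and enzyme–substrate complex c,

    ṡ = f₁(s, c) = −k₁e₀s + (k₁s + k₋₁)c
    ċ = f₂(s, c) =  k₁e₀s − (k₁s + k₋₁ + k₂)c,

with total enzyme e₀ and typical initial data (s₀, 0). Free enzyme and
product are eliminated through the conservation laws e = e₀ − c and
p = s₀ − s − c; the identity f₁ + f₂ = −k₂c expresses that total
substrate s + c is consumed only by catalysis. Three derived
concentration scales organise everything:

    K_S = k₋₁/k₁          complex equilibrium constant
    K_M = (k₋₁ + k₂)/k₁   Michaelis constant
    K   = k₂/k₁           Van Slyke–Cullen constant,  K = K_M − K_S.

### The pseudo-first-order approximation

At low initial substrate the quadratic terms k₁sc are negligible and
the dynamics are approximated by the linear system with matrix Df(0) =
k₁[[−e₀, K_S], [e₀, −K_M]]. Df(0), together with the comparison
matrices G (K_M → K_M + s₀) and H (K_S → K_S + s₀), belongs to the
Metzler family [[−α, β], [α, −γ]] with positive entries. Its
discriminant Δ = (α − γ)² + 4αβ ≥ 4αβ is strictly positive, so the
eigenvalues

    λ₁,₂ = ½(−(α + γ) ± √Δ)

are always real and distinct and no repeated-root branch exists in the
code (a guard still asserts Δ > 0 and fails loudly on invalid input).
We label λ_slow the eigenvalue closer to zero (the +√Δ branch) and
carry explicit slow/fast names everywhere to avoid sign-convention
bugs. Started at (s₀, 0) the solution is the bi-exponential

    s*(t) = s₀/(2√Δ) [(−α+γ+√Δ) e^{λ_slow t} + (α−γ+√Δ) e^{λ_fast t}]
    c*(t) = s₀ α/√Δ  [e^{λ_slow t} − e^{λ_fast t}].

The implementation derives these amplitudes from the
eigen-decomposition rather than transcribing a display formula, and the
test suite cross-checks them against two independent oracles (matrix
exponential, direct numerical integration of the linear ODE).

### Comparison envelopes

On the compact region D = {s ≥ 0, 0 ≤ c ≤ e₀, s + c ≤ s₀} the
off-diagonal Jacobian entries k₁s + k₋₁ and k₁(e₀ − c) are
nonnegative: the system is cooperative, and Kamke's comparison theorem
applies. The G-flow bounds the nonlinear solution from below and the
H-flow from above, component-wise, for all forward time — provided
s₀ < K strictly. At s₀ = K the matrix H is singular (det H =
k₁²e₀(K − s₀)) and beyond it H has a positive eigenvalue, so the upper
curves grow without bound; the validity flag is therefore the strict
inequality. Because G and H differ from Df(0) by O(s₀) entries, the
envelope width is O(s₀) relative to s₀, i.e. the absolute error of the
linear approximation is O(s₀²). `convergence_study` measures this
exponent empirically as a log–log least-squares slope and reports the
empirical constant Ĉ = max(error/s₀²); Ĉ is a measured stand-in for
the theoretical constant, which is not derived here.

"Sup over [0, ∞)" is approximated by the sup over the sampling grid;
the horizon of 12 slow e-folds leaves all five curves below 10⁻⁵ of
their initial scale, so the tail contribution is negligible at the
tolerances used (documented, not proven in code).

### Timescale separation

Linearity does not imply timescale separation. In the derived
constants, Δ = k₁²((K_M + e₀)² − 4Ke₀), which gives the equivalent
eigenvalue form λ₁,₂ = (k₁/2)(K_M + e₀)(−1 ± √(1 − η)) with the
dimensionless separation index

    η = 4Ke₀/(K_M + e₀)² ∈ (0, 1].

Small η (notably: e₀ ≪ K_M, or K ≪ K_M) separates the two decay modes;
η → 1 (K_S ≈ 0 with K_M ≈ e₀) makes them equal and no one-dimensional
reduction is accurate. Under separation the slow eigenvalue is
approximated to first order in η by −k₂e₀/(K_M + e₀) (Taylor remainder
O(η²), bounded in the tests by (k₁/2)(K_M + e₀)·η²/2·(1 − η)^{−1/2}),
the reduced model is a single exponential decay at that rate, and the
slow eigenspace is asymptotic to span(K_M − Ke₀/(K_M + e₀), e₀).

The "separated" verdict uses a configurable policy threshold η ≤ 0.1
(the theory states only "much less than 1"); the threshold is echoed in
every report. The reduced model is applied to the caller's raw initial
point by default, with the slow-eigenspace projection available as an
option: the projection is the asymptotically correct reduction (it also
tracks the complex channel), while the raw mode preserves the caller's
initial data exactly; the theory does not single out one of the two,
so both are provided and labelled.

## Parameter estimation

Because the model solution is an explicit bi-exponential, estimating
(k₁, k₋₁, k₂) from a progress curve needs no ODE solver in the loop:

1. **Fit** y(t) ≈ A₁e^{λ₁t} + A₂e^{λ₂t} (for the complex channel the
   structurally constrained form A(e^{λ₁t} − e^{λ₂t})). The optimizer
   searches only the two rates, parametrized as λ₁ = −exp(p₁),
   λ₂ = λ₁ − exp(p₂) so that λ₂ < λ₁ < 0 throughout, with bounds set
   by the data's sampling interval and observation window; the
   amplitudes are solved by linear least squares at every step
   (variable projection). Initialization is by exponential peeling —
   log-linear fit of the tail for the slow rate, then of the
   early-time remainder for the fast rate — plus two scale-based
   fallback starts; the best residual wins. Non-convergence is
   reported as a flag plus message, never as silent numbers.
2. **Invert** algebraically. With s₀ and e₀ known (the experimental
   design quantities), trace and determinant give α + γ and α(γ − β),
   and the amplitude structure fixes α: for the c channel
   α = A(λ₁ − λ₂)/s₀; for the s channel the amplitude asymmetry gives
   γ − α = (A₁ − A₂)(λ₁ − λ₂)/s₀. Then k₁ = α/e₀, k₂ = λ₁λ₂/α,
   k₋₁ = −(λ₁ + λ₂) − α − k₂. The inversion is exact on noiseless
   linear-model input.

The total-substrate channel s̄ = s + c (and the product channel
s₀ − s̄) is a bi-exponential whose amplitudes are determined by the two
rates alone, so it identifies only two of the three constants;
recovery from those channels raises an identifiability error rather
than returning an arbitrary solution.

Standard errors are residual-based: covariance of (rates, amplitudes)
from the local linearization of the fit, propagated to the rate
constants by the delta method through the inversion map. They are
rough errors — homoscedastic uncorrelated noise, no small-sample
correction.

### Estimator precision

The information content of a single observed channel limits the
attainable precision. For the reference conditions (all rate constants
and e₀ equal to 1, s₀ = 0.1, complex channel, additive noise with
sd = 1 % of s₀, 200 samples), the Cramér–Rao bound puts the standard
error of k₋₁ near 5 % for any standard sampling design — k₋₁ is the
weakest-identified constant from c(t) — while k₁ and k₂ sit near
1.5 %. Monte Carlo of the implemented estimator matches this bound
(median max-relative-error ≈ 3.8 %, 95th percentile ≈ 11 %), i.e. the
estimator is statistically efficient here; tighter recovery requires
lower noise, more samples, or a second observed channel.

## Synthetic data

`generate_synthetic` simulates either the linear closed form (exact
round-trip target) or the full nonlinear system (to probe
misspecification bias, which shrinks as s₀/K decreases), then adds
i.i.d. additive homoscedastic Gaussian noise to the chosen channel.
The noise model is a deliberate simplification that keeps the
estimator's statistical behaviour analyzable: real assay noise is often
signal-dependent and autocorrelated, negative concentrations are not
truncated by default (an opt-in truncation flag exists), and
instrument drift/baseline offsets are not emulated. Passing
tests therefore demonstrate correctness of the mathematics and
efficiency under the stated noise model, not robustness to real
instrument artefacts. Every stochastic path requires an explicit seed;
there is no hidden global RNG state.

## Numerical choices

* **Time grid** — t = 0 followed by 400 geometrically spaced points on
  [10⁻⁴T, T] with T = 12/|λ_slow| of the linearization (slow mode
  decayed to ~6·10⁻⁶). One grid resolves both the fast transient and
  the slow tail; λ_slow of Df(0) does not depend on s₀, so sweeps over
  s₀ share the same horizon.
* **Integration** — stiff-capable LSODA with analytic Jacobian;
  rtol 10⁻¹⁰/atol 10⁻¹² where trajectories feed error measurements
  (the measured error is O(s₀²) and the solver error must sit far
  below it), looser 10⁻⁸/10⁻¹⁰ defaults on the CLI.
* **Ordering checks** — the eight envelope inequalities are non-strict
  and tested with tolerance 10⁻⁷ (solver noise floor × safety factor).
* **Convergence study** — requires ≥ 4 strictly decreasing s₀ values,
  each ≤ K/2 (for a list of parameter sets the ceiling is
  K*/2 = min(k₂/k₁)/2 over the list, computed not assumed); the
  acceptance sweep uses s₀ ∈ {0.2, 0.1, 0.05, 0.025, 0.0125}.
* **Degenerate inputs** — zero/constant observable series, fewer than
  8 samples, non-monotone time grids, and non-positive recovered
  constants are all rejected with named errors.
* **Grades and thresholds** — the linearization grade (s₀/K ≤ 0.1
  "good", ≤ 0.5 "marginal", < 1 "poor", else "invalid-for-bounds") is
  implementation policy, configurable, and clearly separated from the
  theory-backed strict validity condition s₀ < K.

## Scope and limitations

* Irreversible mechanism only: no product rebinding, no inhibitors, no
  cooperativity, no time-varying parameters.
* No stochastic (Gillespie) simulation; concentrations are continuous.
* The envelope semantics require the typical initial condition
  (s₀, 0); trajectories from other initial points in D are supported
  exactly but carry no bounding guarantee.
* The fitting path estimates the three rate constants only; s₀ and e₀
  are required knowns, as in a real assay. No Bayesian inference, and
  no fitting of the full nonlinear model — the package demonstrates
  the linear route.
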
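# pfokinetics

Pseudo-first-order kinetics for the irreversible Michaelis–Menten
reaction at low substrate: closed-form solutions, rigorous comparison
envelopes, timescale-separation diagnostics, and direct rate-constant
estimation from progress curves.

## The problem

The Michaelis–Menten mechanism E + S ⇌ C → E + P is governed by the
planar mass-action system

```
ṡ = −k₁e₀s + (k₁s + k₋₁)c
ċ =  k₁e₀s − (k₁s + k₋₁ + k₂)c,        s(0) = s₀, c(0) = 0,
```

which has no elementary solution. When the **initial substrate**
concentration is small — specifically s₀ ≪ K, where K = k₂/k₁ is the
Van Slyke–Cullen constant — the dynamics are globally approximated by
the linear (pseudo-first-order) system obtained from the Jacobian at
the origin, whose solution is an explicit bi-exponential. This regime
is distinct from the classical low-enzyme quasi-steady-state reduction:
it requires no timescale separation at all, and the validity condition
is independent of e₀.

The package implements that theory end to end:

* **Exact linear solutions** — the linearization Df(0) and the two
  comparison matrices G (lower) and H (upper), all of the Metzler form
  [[−α, β], [α, −γ]], with closed-form eigenstructure and
  bi-exponential trajectories.
* **Rigorous envelopes** — because the nonlinear system is cooperative
  on its invariant region, Kamke's comparison theorem brackets its
  solution component-wise between the G- and H-flows whenever s₀ < K;
  the envelope verification checks all eight bracketing inequalities
  pointwise.
* **Convergence measurement** — the sup-norm error of the linear
  approximation is of order s₀²; `convergence_study` measures the
  empirical exponent over an s₀ sweep.
* **Timescale analysis** — separation of the two decay modes is
  governed by η = 4Ke₀/(K_M + e₀)²; the package reports η, the
  first-order slow eigenvalue −k₂e₀/(K_M + e₀), the reduced
  one-dimensional model, and the slow-eigenspace comparison.
* **Parameter estimation** — the closed form makes rate-constant
  estimation a bi-exponential fit plus an exact algebraic inversion
  (no stiff ODE solving inside an optimizer), exposed as a
  statsmodels-style `ProgressCurveModel` / `ProgressCurveResults`
  pair, with a synthetic-data generator for validation.

## Worked example

```python
import pfokinetics as pk

p = pk.ReactionParameters(k1=1.0, k_minus1=1.0, k2=1.0, e0=1.0, s0=0.1)

rep = pk.validity_report(p)            # s0/K = 0.1, grade: "good"
es, ec = pk.approximation_error(p)     # sup-norm gap full vs linear
print(f"sup|s - s*| = {es:.3e}   sup|c - c*| = {ec:.3e}")
# sup|s - s*| = 7.571e-04   sup|c - c*| = 4.322e-04

ts = pk.timescale_report(p)
print(f"eta = {ts.eta:.4f}  lambda_slow = {ts.lambda_slow_exact:.6f}")
# eta = 0.4444  lambda_slow = -0.381966   (approx -0.3333, not separated)
```

At s₀ = 0.1 the linear approximation tracks the full solution to within
about 8·10⁻⁴ concentration units (0.8 % of s₀) uniformly in time, even
though η = 4/9 means there is *no* usable timescale separation — the
approximation does not need one.

Estimating the rate constants back from a noisy synthetic complex
progress curve (noise sd = 1 % of s₀):

```python
ds = pk.generate_synthetic(p, observable="c", noise_sd=0.001, seed=42)
res = pk.ProgressCurveModel(ds.t, ds.y, "c", s0=0.1, e0=1.0).fit()
print(res.summary())
```

```
Pseudo-first-order progress-curve fit
=====================================================
Observable:        c
N observations:    401
Known s0, e0:      0.1, 1
Converged:         True
Residual RMS:      9.4840e-04
-----------------------------------------------------
parameter             estimate         std err
-----------------------------------------------------
lambda_slow          -0.375655         0.00668
lambda_fast           -2.63055          0.0468
k1                     0.99805          0.0101
k_minus1               1.01805          0.0381
k2                    0.990109         0.00997
=====================================================
```

All three microscopic constants are recovered to about 1–2 % from a
single noisy curve, using only the known assay quantities s₀ and e₀.

A command-line interface mirrors the library:

```bash
pfokinetics simulate --k1 1 --km1 1 --k2 1 --e0 1 --s0 0.1 --model full
pfokinetics bounds   --k1 1 --km1 1 --k2 1 --e0 1 --s0 0.5
pfokinetics timescales --k1 1 --km1 1 --k2 1 --e0 1 --s0 0.1
```

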
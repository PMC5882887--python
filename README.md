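# grnest

Robust H∞ state estimation for **discrete-time stochastic genetic
regulatory networks** (GRNs) with leakage, distributed, and probabilistic
measurement delays.

In a GRN, mRNA concentrations `x(k)` drive protein synthesis and the
proteins `y(k)` feed back on transcription through a Hill-type regulation
function.  Only noisy, intermittently delayed measurements of either channel
are available, so the concentrations must be reconstructed by an observer.
`grnest` is for researchers in systems biology and networked control who
want to

* **simulate** the coupled delayed stochastic dynamics

  ```
  x(k+1) = -(A+ΔA) x(k-ρ₁) + (B+ΔB) ĝ(y(k-δ(k))) + (E+ΔE) Σₛ μₛ h(y(k-s))
           + σ(k, x(k-ρ₁)) ω(k) + Lx vx(k)
  y(k+1) = -(C+ΔC) y(k-ρ₂) + (D+ΔD) x(k-τ(k)) + (F+ΔF) Σₙ ξₙ x(k-n)
           + Ly vy(k)
  ```

  together with the linear estimator `x̂(k+1) = -Aₓ x̂(k) + Bₓ Z̃ₓ(k)` fed
  through a Bernoulli-dropout measurement channel
  `Z̃ₓ(k) = αₖ M x(k) + (1-αₖ) M x(k-1)`,

* **synthesize** estimator gains by assembling and solving the
  delay-dependent stability / disturbance-attenuation **LMIs** (linear
  matrix inequalities), with gains recovered from the change of variables
  `Aₓ = R₂₁⁻¹X₁`, `Bₓ = R₂₁⁻¹X₂`, `A_y = R₂₂⁻¹Y₁`, `B_y = R₂₂⁻¹Y₂`, and

* **verify** mean-square exponential stability
  (`E{|x̄(k)|²+|ȳ(k)|²} ≤ α μᵏ`, `μ < 1`) and the H∞ energy bound
  (`Σₖ E{|x̄|²+|ȳ|²} ≤ γ² Σₖ(|vx|²+|vy|²)`) by Monte-Carlo, sweeping over
  admissible norm-bounded parameter perturbations `Δ·(k) = R N(k) W` with
  `N(k)ᵀN(k) ≤ I`.

The LMI systems are exposed in two fidelities.  **`paper-faithful`** places
every published block with its published sign; several diagonal blocks are
then forced positive semidefinite by the positive-definiteness of the
decision matrices, and the solver certifies infeasibility *analytically*,
naming the offending block.  **`repaired`** is the package's completed
reading of the same derivation (leakage-window terms, a second sector
multiplier, disturbance couplings — see `docs/methods.md`) and is the mode
used for actual gain synthesis.  The SDP backend is a dense spectral solver
(`grnest.sdp`): annealed smoothed worst-eigenvalue minimization over the
affine matrix family, well suited to these ≤ 48×48 blocks.

## Worked example

```python
import numpy as np
from grnest import (SectorBounds, minimize_gamma, random_stable_model,
                    verify_exponential, verify_hinf)
from grnest.simulator import default_disturbances

model = random_stable_model(seed=1, n=2, target_contraction=0.3)
sector = SectorBounds.for_hill(2, h=2.0)

gamma, result = minimize_gamma(model, sector, fidelity="repaired", seed=0)
print(f"gamma = {gamma:.4f}, margins = {min(result.margins):.3f}")

verdict = verify_exponential(model, result.gains, runs=50, horizon=200, seed=3)
print(f"stable = {verdict.stable}, mu = {verdict.decay_factor:.4f}")

hv = verify_hinf(model, result.gains, gamma,
                 disturbance_bank=[lambda K: default_disturbances(K, 2)],
                 runs=20, horizon=150, seed=5)
print(f"max energy ratio = {hv.hinf_ratio:.4f}  (gamma^2 = {gamma**2:.2f})")
```

prints

```
gamma = 1.8063, margins = 0.926
stable = True, mu = 0.2982
max energy ratio = 0.0751  (gamma^2 = 3.26)
```

The minimized attenuation level γ ≈ 1.81 certifies the energy bound; the
fitted mean-square decay rate μ ≈ 0.30 < 1 confirms exponential stability
across the uncertainty sweep (no perturbation, the trigonometric diagonal
pattern, and eight seeded random contractions); the worst Monte-Carlo
energy ratio 0.075 sits far below γ² = 3.26, as a sufficient-condition
certificate predicts.

Two published two-gene parameter sets ship as fixtures
(`example_4_1("4.1a")`, `example_4_1("4.1b")`, `example_4_2()`), including
the published candidate gains.  Note that the published feasible solution is
not internally consistent with the gain-recovery formula (the package tests
document this), so no numerical comparison is built on it.

## Command line

```sh
grnest fixtures export --name 4.1a --out model.yaml
grnest simulate --config model.yaml --horizon 100 --runs 3 --seed 1 --out runs/
grnest synthesize --fixture 4.1b --mode synth --fidelity repaired --out gains.yaml
grnest verify --fixture 4.1b --gains gains.yaml --runs 100 --seed 1
grnest check --trials 1000
```

Exit codes distinguish success (0), LMI infeasibility (3), and failed
stability/attenuation verification (4).  Every run writes a manifest with
the config hash, seed, and package version.

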
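# Methods

## Model

The package implements a discrete-time stochastic genetic regulatory
network over `n` genes.  mRNA concentrations `x(k) ∈ R^n` and protein
concentrations `y(k) ∈ R^n` evolve as

```
x(k+1) = -(A+ΔA(k)) x(k-ρ₁) + (B+ΔB(k)) ĝ(y(k-δ(k)))
         + (E+ΔE(k)) Σ_{s≥1} μ_s h(y(k-s)) + σ(k, x(k-ρ₁)) ω(k) + Lx vx(k)
y(k+1) = -(C+ΔC(k)) y(k-ρ₂) + (D+ΔD(k)) x(k-τ(k))
         + (F+ΔF(k)) Σ_{n≥1} ξ_n x(k-n) + Ly vy(k)
```

* `A, C` — diagonal degradation rates (strictly positive); `D` — diagonal
  translation rates (non-negative, so fully decoupled test systems remain
  constructible); `B` — the transcription coupling matrix; `E, F` —
  distributed-delay weights.
* `ρ₁, ρ₂` — integer *leakage* delays in the degradation terms; `δ(k),
  τ(k)` — integer time-varying delays inside known bounds `[δ_m, δ_M]`,
  `[τ_m, τ_M]`.  Delay schedules must evaluate to integers exactly;
  non-integer values are rejected rather than rounded, since silent
  rounding can escape the declared bounds.
* `μ_s, ξ_n` — summable distributed-delay kernels.  The default family is
  exponential, `μ_s = e^(-c s)`, whose total and tail masses are closed
  form.  The infinite sums are truncated at relative tail mass `rel_tol`
  (default 1e-12); states preceding the supplied history window count as
  zero, so the truncation error is bounded by the kernel tail.
* `ĝ = h` — Hill regulation `g(s) = s^h/(1+s^h)`.  The dynamics can push
  states below zero, where a Hill law has no meaning; the simulator
  evaluates the regulation on `max(s, 0)` (negative concentrations exert
  no activation).  The clipped map is monotone on all of R with slopes in
  `[0, max-slope]`, so it satisfies the same sector bound as the Hill curve
  itself; for `h = 2` the maximal slope is `3√3/8 ≈ 0.6495`.
* `σ(k, x)` — noise intensity constrained by `σᵀσ ≤ xᵀHx` with `H ≻ 0`.
  Only the bound is part of the model; the default concrete form is
  `σ(x) = H^{1/2} x` (bound tight), and any user-supplied factor is checked
  against the bound at construction.  `ω(k)` is specified only through
  `E ω = 0`, `E ω² = 1`, no correlation; it is implemented as i.i.d.
  standard normal draws, which is all the second-moment analysis uses.
* Parameter uncertainty `Δ·(k) = R N(k) W_i` with `N(k)ᵀN(k) ≤ I`.  Two
  generators are provided: the deterministic trigonometric diagonal
  `N(k) = diag(sin kπ/2, cos kπ/2, …)` used in the worked examples, and
  seeded random contractions (random orthogonal pair × singular values in
  (0,1]) — robustness quantifies over *all* admissible `N(k)`, so sweeps
  should not be restricted to one pattern.

Measurements `Zx = Mx`, `Zy = Ny` reach the estimator either current or one
step old: `Z̃x(k) = αₖ Zx(k) + (1-αₖ) Zx(k-1)` with i.i.d. Bernoulli
`αₖ ∈ {0,1}`, `P(αₖ=1) = α₀` (and `βₖ, β₀` for the y channel).  The
measurement needed at `k = 0` comes from the history state at `-1`.  The
estimator is linear: `x̂(k+1) = -Aₓ x̂(k) + Bₓ Z̃ₓ(k)`, likewise for `ŷ`.
The estimation errors `x̃ = x - x̂`, `ỹ = y - ŷ` obey a closed recursion
that the simulator can propagate independently; agreement with the
subtraction of the two simulated systems is an exact identity and is
enforced in the tests to 1e-10 relative.

Randomness is partitioned per role (process noise, the two dropout
streams, uncertainty, histories) from one master seed, so toggling one
noise source never shifts another's draws.

## Stability and attenuation conditions

Stability is certified through a Lyapunov–Krasovskii functional over the
delay windows, yielding two block LMIs `Λ₁ < 0`, `Λ₂ < 0` in ten symmetric
positive definite matrices `R₁₁ … R₅₂`, an S-procedure multiplier `λ` for
the sector-bounded regulation, and scalars `ε₁, ε₂` that absorb the
norm-bounded uncertainty via the standard bound
`T̃NW̃ + W̃ᵀNᵀT̃ᵀ ≤ ε⁻¹T̃T̃ᵀ + εW̃ᵀW̃` followed by a Schur complement.
Synthesis replaces the bilinear products `R₂₁Aₓ, R₂₁Bₓ, R₂₂A_y, R₂₂B_y` by
free matrices `X₁, X₂, Y₁, Y₂`; gains are recovered afterwards by linear
solves (never explicit inversion), gated on the conditioning of `R₂₁, R₂₂`
(default threshold 1e8) and on solve residuals.

### The two fidelities

`paper-faithful` assembles every published block with its published sign.
As published the conditions cannot hold: the diagonal blocks `H R₁₁` (x
leakage), `I(R₁₂+R₂₂)`, `I(R₁₁+R₂₁)`, `+μ̄R₅₁`, and a zero block at the y
leakage coordinate are forced positive semidefinite whenever the decision
matrices are positive definite, and a symmetric matrix with a
positive-forced diagonal block is never negative definite.  The solver
detects this by scanning the diagonal blocks over probe assignments that
span the admissible cone and reports the offending block as an analytic
infeasibility certificate, without running the numerical backend.

`repaired` is the package's completed reading of the same derivation.  The
changes, each tied to a specific gap:

1. **Leakage windows.**  The functional contains no sums over the leakage
   windows, so the coordinates `x(k-ρ₁)`, `y(k-ρ₂)` receive no negative
   diagonal mass — yet the Schur rows deposit `2Aᵀ(R₁₁+R₂₁)A`-type positive
   terms there.  New matrices `Q₁, Q₂ ≻ 0` model the missing window terms:
   they enter `ψ₁₁, ψ₁₂` positively (energy at `x(k)`, `y(k)`) and the
   leakage diagonals negatively.  Feasibility then requires, roughly,
   `2‖A‖² < 1` — the correct qualitative condition for a one-step-delayed
   degradation loop.
2. **Noise energy.**  The `sym(H R₁₁)` block is the genuine noise second
   moment and keeps its positive sign (flipping it would reward noise); the
   error recursion also carries the noise, so the repaired block uses
   `sym(H(R₁₁+R₂₁))`.
3. **Distributed-delay aggregates.**  The weighted-series inequality yields
   `-(1/ξ̄)R₅₂` (resp. `-(1/μ̄)R₅₁`) at the aggregate coordinate the `F`
   (resp. `E`) coupling actually touches; the published form parks the
   negative mass on a disconnected coordinate.
4. **Second sector multiplier.**  The positive `μ̄R₅₁` mass at the `h(y(k))`
   coordinate is dominated by tying `h(y(k))` back to `y(k)` through the
   sector bound with a second multiplier `λ₂ > 0`.
5. **Disturbance couplings.**  The published attenuation form leaves the
   disturbance column zero, making `γ` vacuous; repaired mode restores
   `√2(R₁₁+R₂₁)Lx` / `√2(R₁₂+R₂₂)Ly` in the first S-row and adds the `+I`
   output blocks at the (state, error) coordinates that the energy-ratio
   functional requires.
6. **Uncertainty-bound placement.**  `ε W̄ᵀW̄` lands on the coordinates the
   perturbation factors act on (`W₁, W₄, W₆` on the x side; `W₂, W₃, W₅`
   on the y side), instead of the single published `ε₁W₄ᵀW₄` / misplaced
   `ε₂W₂ᵀW₂` terms.

Both fidelities are first-class and logged; the repaired mode is the one
used for synthesis, and its certificates are cross-checked empirically
(below) rather than taken on faith.

### SDP backend

No external semidefinite-programming solver is used.  The constraint
family is affine in the decision vector; `grnest.sdp` extracts the affine
representation exactly (evaluation at the origin and at unit vectors,
itself verified by an affinity check) and minimizes the pooled worst
eigenvalue with an annealed log-sum-exp smoothing (temperatures 1 → 1e-4)
under L-BFGS-B box bounds, warm-starting each stage.  Strict inequalities
are implemented as `⪯ -ε_strict I` with `ε_strict = 1e-7` folded into the
blocks; the R-matrices carry `⪰ 1e-3 I` so gain recovery stays well
conditioned.  A strictly negative final worst eigenvalue certifies
feasibility and is reported as the margin; a non-negative one is reported
as "infeasible (numerical search)" — a local spectral method cannot
distinguish certified infeasibility from failure to converge, which is why
the analytic diagnosis runs first.  The attenuation level is minimized by
geometric bisection on `γ` (phase one leaves `γ²` free to find an upper
bound), warm-starting each solve, to 2% relative.

## Monte-Carlo verification

`verify_exponential` simulates an ensemble (random initial histories in
[0.2, 1]) with disturbances off, averages
`E{|x(k)|²+|x̃(k)|²+|y(k)|²+|ỹ(k)|²}`, and fits the geometric rate `μ` by
least squares on the log after a burn-in of `max(τ_M, δ_M, ρ₁, ρ₂)+1`
steps, stopping the fit window before the series reaches 100× machine
epsilon relative to its peak (log-of-noise-floor guard).  The fitted `μ` is
reported only when the log-linear fit has R² above 0.9; the verdict
requires the upper confidence bound on `μ` to stay below one for every
uncertainty mode in the sweep (default: off, trigonometric, eight seeded
random contractions).  A finite sweep is a falsification surface, not a
proof — the LMI certificate is the sufficiency claim, and the simulation
can only refute it.

`verify_hinf` starts from zero histories as the attenuation definition
requires, simulates each disturbance in the bank (default: the decaying
sinusoids `vx(k) = sin(6k)e^(-0.1k)`, `vy(k) = cos(2k)e^(-0.2k)` of the
worked examples) across the uncertainty sweep, and compares the worst
ensemble energy ratio against `γ²`.  Infinite-horizon sums are truncated at
a horizon where the remaining disturbance energy is negligible (the default
signals decay below 1e-12 relative well before 200 steps).

## Synthetic data and fixtures

`random_stable_model(seed, n, target_contraction)` generates the study's
toy condition: diagonal degradation rates inside `(0.3t, 0.9t)` for target
`t`, couplings rescaled so the worst-case linear gain matrix (regulation
replaced by its maximal slope) has spectral radius ≤ `t`, a small random
SPD noise bound, dropout probabilities 0.9, delay bounds `[0,2]`, leakage
delays 1, and a light uncertainty structure (`R = W_i = 0.05 I`) so
robustness sweeps are nontrivial.  It emulates a *stable, weakly coupled,
mildly noisy* network; it does not emulate stiff or oscillatory gene
circuits, heavy-tailed noise, or measurement models beyond one-step
dropout, so passing tests say nothing about those regimes.

The two published two-gene parameter sets are packaged verbatim (both
printings of the first example, since the source does not say which fed its
solver run).  Quantities the source omits get documented defaults: noise
bound `H = 0.01 I`, measurement matrices `M = N = I` and dropout
probabilities 0.9 where unprinted, and the scalar `μ = ξ = e^{-c}`
printings interpreted as exponential kernels with rate `c`.  The printed
`d₁, d₂, G` have no consumer in the dynamics and are stored unused.  The
published feasible matrices and gains are exposed for inspection, but the
package builds no numerical target on them: LMI feasible sets are not
singletons, and the published `R₂₁⁻¹X₁` does not reproduce the published
`Aₓ` (a test documents this inconsistency).

## Numerical choices and limitations

* Kernel truncation `rel_tol` 1e-12; halving it moves trajectories by less
  than 10·rel_tol·(sup norm) (tested).
* Decay fits need at least 3 usable points and positive series values;
  all-zero ensembles are flagged inconclusive rather than fitted.
* Near-constant log series count as perfect flat fits (the R² of a
  constant is otherwise numerically meaningless).
* `ε_strict` monotonicity (feasible at ε implies feasible at smaller ε) is
  exercised in the tests at three values.
* The spectral solver is local: "infeasible" outside the analytically
  diagnosed cases means "no feasible point found", and is labelled as such.
* Estimator gains from the repaired synthesis tend toward small magnitudes
  on open-loop-stable toys (zero gains are then feasible); the pipeline
  does not attempt to optimize estimation speed, only certified stability
  and attenuation.
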
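"""Monte-Carlo verification of exponential decay and disturbance attenuation.

These routines bridge the LMI certificates to the definitions they certify:
mean-square exponential stability is checked by fitting the geometric decay
rate of the ensemble mean-square augmented error, and the attenuation level
gamma by comparing the worst observed output-to-disturbance energy ratio
against gamma**2.  Both sweep over admissible uncertainty realizations; a
finite sweep is a falsification surface, not a proof.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import EstimatorGains, GRNModel, StabilityVerdict
from .simulator import (
    DelaySchedule,
    ensemble_mean_square,
    hinf_ratio,
    simulate,
)

__all__ = ["verify_exponential", "verify_hinf", "default_uncertainty_sweep"]


def default_uncertainty_sweep(model: GRNModel, n_random: int = 8):
    """Default sweep: no perturbation, the trigonometric diagonal pattern,
    and a handful of seeded random contractions."""
    modes = ["off"]
    if model.uncertainty is not None and not model.uncertainty.is_zero():
        modes.append("paper-trig")
        modes.extend(f"random-contraction:{i}" for i in range(n_random))
    return modes


def _mode_and_seed(mode: str, base_seed: int):
    if mode.startswith("random-contraction:"):
        return "random-contraction", base_seed + 7919 * (1 + int(mode.split(":")[1]))
    return mode, base_seed


def _default_schedule(model: GRNModel) -> DelaySchedule:
    # alternate between the declared bounds so the schedule is exercised
    dm, dM, tm, tM = model.delta_m, model.delta_M, model.tau_m, model.tau_M
    return DelaySchedule(
        delta=lambda k: dm if k % 2 == 0 else dM,
        tau=lambda k: tM if k % 2 == 0 else tm,
    )


def verify_exponential(
    model: GRNModel,
    gains: EstimatorGains,
    runs: int = 100,
    horizon: int = 300,
    seed: int = 0,
    schedule: Optional[DelaySchedule] = None,
    uncertainty_modes: Optional[Sequence[str]] = None,
    noise: bool = True,
    r2_threshold: float = 0.9,
) -> StabilityVerdict:
    """Fit the mean-square decay factor over an ensemble, per uncertainty mode.

    Simulates ``runs`` trajectories with random initial histories and no
    exogenous disturbance, averages the squared augmented error, and fits
    the geometric rate mu on the log scale after a burn-in covering the
    delay window.  Verdict ``stable`` requires the upper confidence bound
    on mu to stay below one for every mode in the sweep.
    """
    if runs < 2:
        raise ValueError("need at least two runs")
    schedule = schedule or _default_schedule(model)
    modes = list(uncertainty_modes or default_uncertainty_sweep(model))
    n = model.n
    burn = max(model.tau_M, model.delta_M, model.rho1, model.rho2) + 1
    master = np.random.SeedSequence(seed)
    hist_rng = np.random.default_rng(master.spawn(1)[0])
    verdict = StabilityVerdict(gamma=None)
    worst_mu, worst_ci = -np.inf, 0.0
    all_stable = True
    any_fit = False
    hist_len = max(model.tau_M, model.delta_M, model.rho1, model.rho2, 1)
    for mode in modes:
        mode_name, mode_seed = _mode_and_seed(mode, seed)
        trajs = []
        for r in range(runs):
            psi = hist_rng.uniform(0.2, 1.0, (hist_len + 1, n))
            phi = hist_rng.uniform(0.2, 1.0, (hist_len + 1, n))
            trajs.append(
                simulate(
                    model, gains, schedule, horizon,
                    seed=mode_seed * 100_003 + r,
                    history=(psi, phi),
                    noise=noise,
                    uncertainty_mode=mode_name,
                )
            )
        series, mu, alpha, r2, ci = ensemble_mean_square(
            trajs, burn_in=burn, r2_threshold=r2_threshold
        )
        if np.max(series) == 0:
            verdict.per_mode[mode] = {"mu": None, "note": "all-zero ensemble"}
            verdict.inconclusive = True
            continue
        verdict.per_mode[mode] = {"mu": mu, "alpha": alpha, "r2": r2, "ci": ci}
        if mu is None:
            all_stable = False
            continue
        any_fit = True
        if mu > worst_mu:
            worst_mu, worst_ci = mu, ci or 0.0
            verdict.decay_factor = mu
            verdict.prefactor = alpha
            verdict.fit_r2 = r2
            verdict.mu_upper = mu + (ci or 0.0)
        if mu + (ci or 0.0) >= 1.0:
            all_stable = False
    if not any_fit:
        verdict.stable = None
        verdict.inconclusive = True
    else:
        verdict.stable = all_stable and not verdict.inconclusive
    return verdict


def verify_hinf(
    model: GRNModel,
    gains: EstimatorGains,
    gamma: float,
    disturbance_bank: Sequence,
    runs: int = 50,
    horizon: int = 200,
    seed: int = 0,
    schedule: Optional[DelaySchedule] = None,
    uncertainty_modes: Optional[Sequence[str]] = None,
    noise: bool = True,
) -> StabilityVerdict:
    """Worst-case Monte-Carlo energy ratio against the level gamma**2.

    Each disturbance in the bank is a callable ``K -> (vx, vy)`` or a pair
    of arrays; trajectories start from zero initial histories as the
    attenuation definition requires.  The verdict holds when the maximal
    ensemble ratio stays at or below gamma**2.
    """
    if len(disturbance_bank) == 0:
        raise ValueError("disturbance bank must not be empty")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    schedule = schedule or _default_schedule(model)
    modes = list(uncertainty_modes or default_uncertainty_sweep(model))
    n = model.n
    hist_len = max(model.tau_M, model.delta_M, model.rho1, model.rho2, 1)
    zero_hist = (np.zeros((hist_len + 1, n)), np.zeros((hist_len + 1, n)))
    worst = -np.inf
    verdict = StabilityVerdict(gamma=gamma)
    for d_i, dist in enumerate(disturbance_bank):
        vxy = dist(horizon) if callable(dist) else dist
        energy = float(np.sum(np.asarray(vxy[0]) ** 2) + np.sum(np.asarray(vxy[1]) ** 2))
        if energy <= 0:
            raise ZeroDivisionError(f"disturbance {d_i} has zero energy")
        for mode in modes:
            mode_name, mode_seed = _mode_and_seed(mode, seed)
            trajs = [
                simulate(
                    model, gains, schedule, horizon,
                    seed=mode_seed * 99_991 + 131 * d_i + r,
                    history=zero_hist,
                    disturbances=vxy,
                    noise=noise,
                    uncertainty_mode=mode_name,
                )
                for r in range(runs)
            ]
            ratio = hinf_ratio(trajs)
            verdict.per_mode[f"dist{d_i}/{mode}"] = {"ratio": ratio}
            worst = max(worst, ratio)
    verdict.hinf_ratio = worst
    verdict.hinf_holds = bool(worst <= gamma**2)
    return verdict
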
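"""Forward simulation of the delayed stochastic GRN and its estimator.

The simulator advances the mRNA/protein recursions together with the linear
estimator and the Bernoulli-dropout measurement channel, keeping the full
delayed history in ring buffers.  The infinite distributed-delay sums are
truncated at a relative tail-mass tolerance; states preceding the supplied
history window are taken as zero, so the truncation error is bounded by the
kernel tail.

Randomness is split per role (process noise, the two dropout streams, and
uncertainty realizations) from a single master seed, so switching one noise
source on or off never shifts the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .model import (
    EstimatorGains,
    GRNModel,
    sample_uncertainty,
)

__all__ = [
    "DelaySchedule",
    "Trajectory",
    "truncate_kernel",
    "simulate",
    "noise_intensity",
    "NoiseIntensity",
    "ensemble_mean_square",
    "hinf_ratio",
    "default_disturbances",
]


# --------------------------------------------------------------------------
# delay schedules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DelaySchedule:
    """Integer-valued time-varying delays ``delta(k)``, ``tau(k)``.

    Values must be integers exactly (no rounding: silently rounding a
    non-integer schedule could leave the declared bounds unnoticed) and must
    stay inside the model's declared delay intervals when simulated.
    """

    delta: Callable[[int], float]
    tau: Callable[[int], float]

    def delta_at(self, k: int) -> int:
        return _as_int_delay(self.delta(k), "delta", k)

    def tau_at(self, k: int) -> int:
        return _as_int_delay(self.tau(k), "tau", k)

    @classmethod
    def constant(cls, delta: int, tau: int) -> "DelaySchedule":
        return cls(delta=lambda k: delta, tau=lambda k: tau)


def _as_int_delay(v: float, name: str, k: int) -> int:
    r = round(float(v))
    if abs(v - r) > 1e-9:
        raise ValueError(f"{name}({k}) = {v} is not an integer")
    if r < 0:
        raise ValueError(f"{name}({k}) = {r} is negative")
    return int(r)


# --------------------------------------------------------------------------
# kernel truncation
# --------------------------------------------------------------------------


def truncate_kernel(kernel, rel_tol: float = 1e-12, max_len: int = 100_000):
    """Truncation length and weights for a summable non-negative kernel.

    Returns ``(s_max, weights)`` with ``weights[i] = kernel(i+1)`` such that
    the dropped tail mass is at most ``rel_tol`` times the total mass.  For
    the exponential family both masses are closed-form; a generic callable is
    accumulated until the increments converge numerically.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    if hasattr(kernel, "total_mass") and hasattr(kernel, "tail_mass"):
        total = kernel.total_mass
        s_max = 1
        while kernel.tail_mass(s_max) > rel_tol * total and s_max < max_len:
            s_max += 1
    else:
        vals = []
        total = 0.0
        s = 1
        while s <= max_len:
            w = float(kernel(s))
            if w < 0:
                raise ValueError("kernel weights must be non-negative")
            vals.append(w)
            total += w
            if w <= 1e-17 * max(total, 1.0) and s > 1:
                break
            s += 1
        else:
            raise ValueError("kernel does not appear summable within max_len terms")
        # shortest prefix with small enough tail
        tail = 0.0
        s_max = len(vals)
        for i in range(len(vals) - 1, 0, -1):
            tail += vals[i]
            if tail > rel_tol * total:
                s_max = i + 1
                break
        else:
            s_max = 1
    weights = np.array([float(kernel(s)) for s in range(1, s_max + 1)])
    return s_max, weights


# --------------------------------------------------------------------------
# noise intensity
# --------------------------------------------------------------------------


class NoiseIntensity:
    """State-proportional noise intensity ``sigma(k, x) = Sigma x``.

    The model only constrains the intensity through the quadratic bound
    ``sigma' sigma <= x' H x``; the default factor is the symmetric square
    root ``Sigma = H^(1/2)`` (bound tight).  A user-supplied factor is
    checked against the bound at construction.
    """

    def __init__(self, Sigma: np.ndarray, H: np.ndarray, tol: float = 1e-9):
        Sigma = np.asarray(Sigma, dtype=float)
        H = np.asarray(H, dtype=float)
        gap = H - Sigma.T @ Sigma
        if np.min(np.linalg.eigvalsh((gap + gap.T) / 2)) < -tol:
            raise ValueError("Sigma' Sigma exceeds the noise bound H")
        self.Sigma = Sigma

    @classmethod
    def from_bound(cls, H: np.ndarray) -> "NoiseIntensity":
        H = np.asarray(H, dtype=float)
        w, V = np.linalg.eigh(H)
        root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
        return cls(root, H)

    def __call__(self, x_lagged: np.ndarray) -> np.ndarray:
        return self.Sigma @ x_lagged


def noise_intensity(x_lagged: np.ndarray, Sigma: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Evaluate a bound-checked state-proportional noise intensity."""
    return NoiseIntensity(Sigma, H)(x_lagged)


# --------------------------------------------------------------------------
# trajectory record
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-indexed record of one simulation run.

    Arrays are indexed so that row ``k`` holds time step ``k`` for
    ``k = 0 .. horizon``; the pre-history occupies ``history_x`` /
    ``history_y`` with row ``j`` holding time ``-(hist_len - j)``.
    """

    x: np.ndarray
    y: np.ndarray
    xhat: np.ndarray
    yhat: np.ndarray
    Zx: np.ndarray
    Zy: np.ndarray
    Zx_tilde: np.ndarray
    Zy_tilde: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    omega: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    history_x: np.ndarray
    history_y: np.ndarray
    xerr_direct: Optional[np.ndarray] = None
    yerr_direct: Optional[np.ndarray] = None

    @property
    def xerr(self) -> np.ndarray:
        return self.x - self.xhat

    @property
    def yerr(self) -> np.ndarray:
        return self.y - self.yhat

    @property
    def horizon(self) -> int:
        return self.x.shape[0] - 1

    def error_energy(self) -> np.ndarray:
        """Per-step squared augmented error |xbar(k)|^2 + |ybar(k)|^2.

        The augmented states stack the true state with the estimation error.
        """
        return (
            np.sum(self.x**2, axis=1)
            + np.sum(self.xerr**2, axis=1)
            + np.sum(self.y**2, axis=1)
            + np.sum(self.yerr**2, axis=1)
        )

    def to_table(self) -> np.ndarray:
        """One row per time step: k, x, y, xhat, yhat, xerr, yerr, alpha, beta."""
        k = np.arange(self.x.shape[0])[:, None]
        return np.hstack(
            [k, self.x, self.y, self.xhat, self.yhat, self.xerr, self.yerr,
             self.alpha[:, None], self.beta[:, None]]
        )


# --------------------------------------------------------------------------
# the simulator
# --------------------------------------------------------------------------


def _spawn_streams(seed) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("omega", "alpha", "beta", "uncertainty", "history")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def default_disturbances(horizon: int, n: int, variant: str = "4.1a"):
    """The decaying sinusoid disturbance pair used by the worked examples.

    ``vx(k) = sin(6k) e^(-0.1k)``; ``vy(k) = cos(2k) e^(-0.2k)`` for the
    system variants, ``cos(2k) e^(-0.1k)`` for the error-system variant.
    Broadcast to all n coordinates.
    """
    k = np.arange(horizon + 1)
    vx = np.sin(6 * k) * np.exp(-0.1 * k)
    rate = 0.1 if variant == "4.1b" else 0.2
    vy = np.cos(2 * k) * np.exp(-rate * k)
    return np.tile(vx[:, None], (1, n)), np.tile(vy[:, None], (1, n))


def simulate(
    model: GRNModel,
    gains: EstimatorGains,
    schedule: DelaySchedule,
    horizon: int,
    seed=0,
    disturbances: Optional[tuple[np.ndarray, np.ndarray]] = None,
    history: Optional[tuple[np.ndarray, np.ndarray]] = None,
    noise: bool = True,
    noise_factor: Optional[NoiseIntensity] = None,
    uncertainty_mode: str = "off",
    kernel_rel_tol: float = 1e-12,
    track_error_recursion: bool = False,
) -> Trajectory:
    """Run the coupled GRN / estimator recursions for ``horizon`` steps.

    ``history`` supplies the initial state windows ``(psi, phi)`` as arrays
    of shape (hist_len+1, n) covering times ``-hist_len .. 0`` (row order:
    oldest first); if omitted, the history is zero except a unit state at
    time 0.  ``disturbances`` is a pair of (horizon+1, n) arrays; omitted
    means no exogenous input.  With ``track_error_recursion`` the estimation
    error is additionally propagated through its own closed recursion (the
    defining identity), stored in ``xerr_direct`` / ``yerr_direct``.
    """
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    n = model.n
    streams = _spawn_streams(seed)

    s_max_mu, mu_w = truncate_kernel(model.mu_kernel, kernel_rel_tol)
    s_max_xi, xi_w = truncate_kernel(model.xi_kernel, kernel_rel_tol)

    hist_len = max(model.tau_M, model.delta_M, model.rho1, model.rho2, 1)
    if history is None:
        psi = np.zeros((hist_len + 1, n))
        phi = np.zeros((hist_len + 1, n))
        psi[-1] = 1.0
        phi[-1] = 1.0
    else:
        psi = np.asarray(history[0], dtype=float)
        phi = np.asarray(history[1], dtype=float)
        if psi.ndim == 1:
            psi = np.tile(psi[None, :], (hist_len + 1, 1))
        if phi.ndim == 1:
            phi = np.tile(phi[None, :], (hist_len + 1, 1))
        if psi.shape[0] < hist_len + 1:
            pad = np.zeros((hist_len + 1 - psi.shape[0], n))
            psi = np.vstack([pad, psi])
        if phi.shape[0] < hist_len + 1:
            pad = np.zeros((hist_len + 1 - phi.shape[0], n))
            phi = np.vstack([pad, phi])
        hist_len = psi.shape[0] - 1

    if disturbances is None:
        vx = np.zeros((horizon + 1, n))
        vy = np.zeros((horizon + 1, n))
    else:
        vx = np.asarray(disturbances[0], dtype=float)
        vy = np.asarray(disturbances[1], dtype=float)
        if vx.ndim == 1:
            vx = np.tile(vx[:, None], (1, n))
        if vy.ndim == 1:
            vy = np.tile(vy[:, None], (1, n))

    if noise and noise_factor is None:
        noise_factor = NoiseIntensity.from_bound(model.H)

    # full state tape over -hist_len .. horizon; lookup(t) = 0 before that
    offset = hist_len
    X = np.zeros((hist_len + horizon + 1, n))
    Y = np.zeros((hist_len + horizon + 1, n))
    X[: hist_len + 1] = psi
    Y[: hist_len + 1] = phi

    def x_at(t: int) -> np.ndarray:
        i = t + offset
        return X[i] if i >= 0 else np.zeros(n)

    def y_at(t: int) -> np.ndarray:
        i = t + offset
        return Y[i] if i >= 0 else np.zeros(n)

    # activation tape g(y(t)) aligned with Y; filled as states are produced,
    # so the distributed sums reduce to one windowed dot product per step
    g = model.activation
    GY = np.zeros_like(Y)
    GY[: hist_len + 1] = g(Y[: hist_len + 1])

    def _windowed_sum(tape: np.ndarray, k: int, w: np.ndarray) -> np.ndarray:
        # sum_{s=1..len(w)} w[s-1] * tape_row(k - s); rows before the tape
        # start are zero states
        hi = k + offset           # row index of time k-1 is hi-1
        lo = hi - len(w)
        if hi <= 0:
            return np.zeros(tape.shape[1])
        if lo < 0:
            return w[: hi][::-1] @ tape[0:hi] if hi > 0 else np.zeros(tape.shape[1])
        return w[::-1] @ tape[lo:hi]

    l = model.l
    xhat = np.zeros((horizon + 1, n))
    yhat = np.zeros((horizon + 1, n))
    Zx = np.zeros((horizon + 1, l))
    Zy = np.zeros((horizon + 1, l))
    Zx_t = np.zeros((horizon + 1, l))
    Zy_t = np.zeros((horizon + 1, l))
    alpha = np.zeros(horizon + 1)
    beta = np.zeros(horizon + 1)
    omega = np.zeros(horizon + 1)

    # estimator starts at the true initial state unless it is the all-zero run
    xhat[0] = 0.0
    yhat[0] = 0.0

    xerr_d = yerr_d = None
    if track_error_recursion:
        xerr_d = np.zeros((horizon + 1, n))
        yerr_d = np.zeros((horizon + 1, n))
        xerr_d[0] = X[offset] - xhat[0]
        yerr_d[0] = Y[offset] - yhat[0]

    alpha_draws = (
        streams["alpha"].random(horizon + 1) < model.alpha0
        if model.alpha0 < 1.0
        else np.ones(horizon + 1, dtype=bool)
    )
    beta_draws = (
        streams["beta"].random(horizon + 1) < model.beta0
        if model.beta0 < 1.0
        else np.ones(horizon + 1, dtype=bool)
    )
    omega_draws = streams["omega"].standard_normal(horizon + 1) if noise else None

    for k in range(horizon + 1):
        xk = x_at(k)
        yk = y_at(k)
        Zx[k] = model.M @ xk
        Zy[k] = model.N @ yk
        a_k = float(alpha_draws[k])
        b_k = float(beta_draws[k])
        alpha[k] = a_k
        beta[k] = b_k
        # previous measurement at k=0 comes from the history state at -1
        Zx_prev = Zx[k - 1] if k >= 1 else model.M @ x_at(-1)
        Zy_prev = Zy[k - 1] if k >= 1 else model.N @ y_at(-1)
        Zx_t[k] = a_k * Zx[k] + (1.0 - a_k) * Zx_prev
        Zy_t[k] = b_k * Zy[k] + (1.0 - b_k) * Zy_prev

        if k == horizon:
            break

        if model.uncertainty is not None and uncertainty_mode != "off":
            dA, dB, dC, dD, dE, dF = sample_uncertainty(
                model.uncertainty, k, uncertainty_mode, streams["uncertainty"]
            )
        else:
            dA = dB = dC = dD = dE = dF = 0.0

        # distributed sums, truncated; pre-window states are zero
        dist_x = _windowed_sum(GY, k, mu_w)
        dist_y = _windowed_sum(X, k, xi_w)

        delta_k = schedule.delta_at(k)
        tau_k = schedule.tau_at(k)
        if not (model.delta_m <= delta_k <= model.delta_M):
            raise ValueError(
                f"delta({k}) = {delta_k} violates bounds "
                f"[{model.delta_m}, {model.delta_M}]"
            )
        if not (model.tau_m <= tau_k <= model.tau_M):
            raise ValueError(
                f"tau({k}) = {tau_k} violates bounds [{model.tau_m}, {model.tau_M}]"
            )

        sig = (
            noise_factor(x_at(k - model.rho1))
            if noise
            else np.zeros(n)
        )
        w_k = float(omega_draws[k]) if noise else 0.0
        omega[k] = w_k

        x_next = (
            -(model.A + dA) @ x_at(k - model.rho1)
            + (model.B + dB) @ g(y_at(k - delta_k))
            + (model.E + dE) @ dist_x
            + sig * w_k
            + model.Lx @ vx[k]
        )
        y_next = (
            -(model.C + dC) @ y_at(k - model.rho2)
            + (model.D + dD) @ x_at(k - tau_k)
            + (model.F + dF) @ dist_y
            + model.Ly @ vy[k]
        )
        X[k + 1 + offset] = x_next
        Y[k + 1 + offset] = y_next
        GY[k + 1 + offset] = g(y_next)

        xhat[k + 1] = -gains.Ax @ xhat[k] + gains.Bx @ Zx_t[k]
        yhat[k + 1] = -gains.Ay @ yhat[k] + gains.By @ Zy_t[k]

        if track_error_recursion:
            # closed error recursion; must coincide with x - xhat exactly
            xerr_d[k + 1] = (
                -(model.A + dA) @ x_at(k - model.rho1)
                + (gains.Ax - a_k * gains.Bx @ model.M) @ xk
                + (model.B + dB) @ g(y_at(k - delta_k))
                + (model.E + dE) @ dist_x
                + sig * w_k
                - gains.Ax @ xerr_d[k]
                - (1.0 - a_k) * gains.Bx @ (model.M @ x_at(k - 1))
                + model.Lx @ vx[k]
            )
            yerr_d[k + 1] = (
                -(model.C + dC) @ y_at(k - model.rho2)
                + (gains.Ay - b_k * gains.By @ model.N) @ yk
                + (model.D + dD) @ x_at(k - tau_k)
                + (model.F + dF) @ dist_y
                - gains.Ay @ yerr_d[k]
                - (1.0 - b_k) * gains.By @ (model.N @ y_at(k - 1))
                + model.Ly @ vy[k]
            )

    return Trajectory(
        x=X[offset:].copy(),
        y=Y[offset:].copy(),
        xhat=xhat,
        yhat=yhat,
        Zx=Zx,
        Zy=Zy,
        Zx_tilde=Zx_t,
        Zy_tilde=Zy_t,
        alpha=alpha,
        beta=beta,
        omega=omega,
        vx=vx,
        vy=vy,
        history_x=psi,
        history_y=phi,
        xerr_direct=xerr_d,
        yerr_direct=yerr_d,
    )


# --------------------------------------------------------------------------
# ensemble statistics
# --------------------------------------------------------------------------


def ensemble_mean_square(
    trajectories: Sequence[Trajectory],
    burn_in: int = 0,
    fit_window: Optional[tuple[int, int]] = None,
    r2_threshold: float = 0.9,
):
    """Ensemble mean of the squared augmented error and its geometric fit.

    Returns ``(series, mu, alpha, r2, mu_ci_halfwidth)``.  The decay factor
    mu is estimated by ordinary least squares on ``log E{.}`` over the fit
    window; ``alpha`` is the implied prefactor at k = 0.  ``mu`` is None when
    the series is degenerate (all zero) or the log-linear fit is poorer than
    ``r2_threshold``.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories for an ensemble")
    K = trajectories[0].horizon
    if any(t.horizon != K for t in trajectories):
        raise ValueError("all trajectories must share the horizon")
    series = np.mean([t.error_energy() for t in trajectories], axis=0)

    if fit_window is None:
        lo = burn_in
        # stop before the noise floor: 100 eps relative to the peak
        floor = 100 * np.finfo(float).eps * np.max(series) if np.max(series) > 0 else 0
        hi = K + 1
        for k in range(lo, K + 1):
            if series[k] <= floor:
                hi = k
                break
    else:
        lo, hi = fit_window
    window = np.arange(lo, hi)
    vals = series[lo:hi]
    if len(window) < 3 or np.any(vals <= 0):
        return series, None, None, None, None

    logv = np.log(vals)
    X = np.vstack([window, np.ones_like(window, dtype=float)]).T
    coef, res, *_ = np.linalg.lstsq(X, logv, rcond=None)
    slope, intercept = coef
    pred = X @ coef
    ss_res = float(np.sum((logv - pred) ** 2))
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    # a (near-)constant log series is a perfect flat fit, not a bad one
    degenerate = ss_tot <= 1e-16 * len(window) * (1.0 + np.abs(logv).max()) ** 2
    r2 = 1.0 if degenerate else 1.0 - ss_res / ss_tot
    mu = float(np.exp(slope))
    alpha = float(np.exp(intercept))
    # standard error of the slope -> half-width of a ~95% CI on mu
    dof = max(len(window) - 2, 1)
    s2 = ss_res / dof
    sxx = float(np.sum((window - window.mean()) ** 2))
    se_slope = np.sqrt(s2 / sxx) if sxx > 0 else 0.0
    ci = mu * (np.exp(2.0 * se_slope) - 1.0)
    if r2 < r2_threshold:
        return series, None, None, r2, None
    return series, mu, alpha, r2, ci


def hinf_ratio(trajectories: Sequence[Trajectory]) -> float:
    """Monte-Carlo energy ratio for the disturbance-attenuation bound.

    ``sum_k E{|xbar|^2 + |ybar|^2} / sum_k (|vx|^2 + |vy|^2)`` with zero
    initial conditions.  Raises on zero disturbance energy.
    """
    num = np.mean(
        [float(np.sum(t.error_energy())) for t in trajectories]
    )
    t0 = trajectories[0]
    den = float(np.sum(t0.vx**2) + np.sum(t0.vy**2))
    if den <= 0:
        raise ZeroDivisionError("disturbance energy is zero; ratio undefined")
    return num / den
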
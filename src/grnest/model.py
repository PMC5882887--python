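"""Domain types for discrete-time stochastic genetic regulatory networks.

The model class of interest couples mRNA concentrations ``x(k)`` and protein
concentrations ``y(k)`` through degradation, translation, Hill-type feedback
regulation, and three kinds of delay:

* a *leakage* delay in the degradation (self-feedback) term,
* bounded integer *time-varying* delays in the coupling terms, and
* *distributed* delays -- infinite sums over past states weighted by a
  summable kernel.

Measurements of both channels may arrive one step late at random (Bernoulli
dropout), and all coupling matrices may carry norm-bounded uncertainty
``Delta(k) = R N(k) W_i`` with ``N(k)' N(k) <= I``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "GRNModel",
    "UncertaintyStructure",
    "SectorBounds",
    "StabilityVerdict",
    "ExponentialKernel",
    "hill_activation",
    "verify_sector",
    "sample_uncertainty",
]


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialKernel:
    """Distributed-delay kernel ``w_s = exp(-c * s)``, s = 1, 2, ...

    The total mass has the closed form ``exp(-c) / (1 - exp(-c))``.
    """

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("kernel rate must be positive for summability")

    def __call__(self, s: int) -> float:
        return math.exp(-self.rate * s)

    @property
    def total_mass(self) -> float:
        q = math.exp(-self.rate)
        return q / (1.0 - q)

    def tail_mass(self, s_max: int) -> float:
        """Mass of the tail ``sum_{s > s_max} w_s`` in closed form."""
        q = math.exp(-self.rate)
        return q ** (s_max + 1) / (1.0 - q)


def _as_matrix(a, n: int, m: int, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (n, m):
        raise ValueError(f"{name} must be {n}x{m}, got {a.shape}")
    return a


def _check_symmetric(a: np.ndarray, name: str, tol: float = 1e-10) -> None:
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")


# --------------------------------------------------------------------------
# uncertainty
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertaintyStructure:
    """Norm-bounded uncertainty ``[dA .. dF] = R N(k) [W1 .. W6]``.

    ``R`` is the shared left factor, ``W1..W6`` the per-matrix right factors.
    Admissibility requires every realization ``N(k)`` to be a contraction
    (largest singular value at most one).
    """

    R: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    W4: np.ndarray
    W5: np.ndarray
    W6: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.R).shape[0]
        for name in ("R", "W1", "W2", "W3", "W4", "W5", "W6"):
            object.__setattr__(
                self, name, _as_matrix(getattr(self, name), n, n, name)
            )

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def is_zero(self) -> bool:
        return not np.any(self.R) or not any(
            np.any(getattr(self, f"W{i}")) for i in range(1, 7)
        )

    @property
    def W(self) -> tuple[np.ndarray, ...]:
        return (self.W1, self.W2, self.W3, self.W4, self.W5, self.W6)


def _contraction_factor(
    n: int, k: int, mode: str, rng: Optional[np.random.Generator]
) -> np.ndarray:
    """One admissible realization ``N(k)`` with sigma_max <= 1."""
    if mode == "off":
        return np.zeros((n, n))
    if mode == "paper-trig":
        # diag(sin(k pi/2), cos(k pi/2), sin(k pi/2), ...) -- the alternating
        # diagonal pattern used in the worked examples.
        vals = [
            math.sin(k * math.pi / 2) if i % 2 == 0 else math.cos(k * math.pi / 2)
            for i in range(n)
        ]
        return np.diag(vals)
    if mode == "random-contraction":
        if rng is None:
            raise ValueError("random-contraction mode requires a seeded rng")
        # random orthogonal pair times singular values in (0, 1]
        q1, _ = np.linalg.qr(rng.standard_normal((n, n)))
        q2, _ = np.linalg.qr(rng.standard_normal((n, n)))
        s = rng.uniform(0.0, 1.0, size=n)
        return q1 @ np.diag(s) @ q2
    raise ValueError(f"unknown uncertainty mode {mode!r}")


def sample_uncertainty(
    structure: Optional[UncertaintyStructure],
    k: int,
    mode: str = "off",
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, ...]:
    """Draw the six perturbation matrices ``dA(k) .. dF(k)``.

    Modes: ``off`` (zeros), ``paper-trig`` (deterministic sin/cos diagonal
    contraction), ``random-contraction`` (seeded random orthogonal x scaling).
    Each output equals ``R @ N_k @ W_i`` with ``sigma_max(N_k) <= 1``.
    """
    if structure is None or mode == "off":
        n = 0 if structure is None else structure.n
        if structure is None:
            raise ValueError("sample_uncertainty requires a structure unless mode='off'")
        return tuple(np.zeros((n, n)) for _ in range(6))
    n = structure.n
    N_k = _contraction_factor(n, k, mode, rng)
    return tuple(structure.R @ N_k @ W for W in structure.W)


# --------------------------------------------------------------------------
# sector bounds
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorBounds:
    """Slope bounds for a sector-bounded activation.

    The regulation nonlinearity satisfies, for all x, y,

        [g(x) - g(y) - N1 (x-y)]' [g(x) - g(y) - N2 (x-y)] <= 0,

    with ``N1 - N2`` symmetric positive definite.  The derived matrices
    ``Ntilde1 = (N1'N2 + N2'N1)/2`` and ``Ntilde2 = -(N1' + N2')/2`` feed
    the S-procedure block of the stability conditions.
    """

    N1: np.ndarray
    N2: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.N1).shape[0]
        object.__setattr__(self, "N1", _as_matrix(self.N1, n, n, "N1"))
        object.__setattr__(self, "N2", _as_matrix(self.N2, n, n, "N2"))
        diff = self.N1 - self.N2
        _check_symmetric(diff, "N1 - N2")
        if np.min(np.linalg.eigvalsh((diff + diff.T) / 2)) <= 0:
            raise ValueError("N1 - N2 must be symmetric positive definite")

    @property
    def n(self) -> int:
        return self.N1.shape[0]

    @property
    def Ntilde1(self) -> np.ndarray:
        return (self.N1.T @ self.N2 + self.N2.T @ self.N1) / 2.0

    @property
    def Ntilde2(self) -> np.ndarray:
        return -(self.N1.T + self.N2.T) / 2.0

    @classmethod
    def for_hill(cls, n: int, h: float = 2.0) -> "SectorBounds":
        """Canonical sector for the Hill function ``s^h / (1 + s^h)``.

        The maximal slope of the Hill curve on [0, inf) bounds the sector
        from above; the lower slope is zero (monotone nondecreasing).
        """
        slope = hill_max_slope(h)
        return cls(N1=np.eye(n) * (slope + 5e-4), N2=np.zeros((n, n)))


def hill_activation(s, h: float):
    """Hill regulation ``g(s) = s^h / (1 + s^h)`` on s >= 0.

    Strictly increasing in ``s`` for h > 0, with range [0, 1).  Vectorized
    over ``s``.
    """
    if h <= 0:
        raise ValueError("Hill exponent must be positive")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("Hill activation is defined for non-negative arguments")
    p = np.power(s, h)
    out = p / (1.0 + p)
    return float(out) if out.ndim == 0 else out


def hill_max_slope(h: float, grid: int = 200001, s_hi: float = 10.0) -> float:
    """Maximal derivative of the Hill curve, by dense grid search.

    For h = 2 the maximum is ``3 sqrt(3) / 8`` at ``s = 3^(-1/2)``; the grid
    search reproduces that to ~1e-8 and covers other exponents.
    """
    s = np.linspace(0.0, s_hi, grid)
    p = np.power(s, h, where=s > 0, out=np.zeros_like(s))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = h * np.power(s, h - 1.0, where=s > 0, out=np.zeros_like(s))
        deriv = d / (1.0 + p) ** 2
    return float(np.nanmax(deriv))


def verify_sector(
    activation: Callable[[np.ndarray], np.ndarray],
    N1: np.ndarray,
    N2: np.ndarray,
    grid: Sequence[tuple[np.ndarray, np.ndarray]],
    tol: float = 1e-9,
) -> tuple[bool, float, Optional[tuple[np.ndarray, np.ndarray]]]:
    """Sample-check the sector inequality over a grid of (x, y) pairs.

    Returns ``(holds, worst_violation, worst_pair)`` where the violation is
    the largest positive value of the quadratic form (0 when it never goes
    positive).  The form is symmetric in N1 <-> N2, so the slope order is
    irrelevant here (unlike :class:`SectorBounds`, which canonicalizes it).
    """
    if len(grid) == 0:
        raise ValueError("verify_sector needs a non-empty sample grid")
    N1 = np.asarray(N1, dtype=float)
    N2 = np.asarray(N2, dtype=float)
    worst = -np.inf
    worst_pair = None
    for x, y in grid:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        d = x - y
        gd = np.atleast_1d(activation(x)) - np.atleast_1d(activation(y))
        val = float((gd - N1 @ d) @ (gd - N2 @ d))
        if val > worst:
            worst, worst_pair = val, (x, y)
    return worst <= tol, max(worst, 0.0), worst_pair


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------


@dataclass
class GRNModel:
    """All parameters of the delayed stochastic GRN and its measurements.

    State recursions (uncertainty terms optional):

        x(k+1) = -(A+dA) x(k-rho1) + (B+dB) g(y(k-delta(k)))
                 + (E+dE) sum_s mu_s h(y(k-s)) + sigma(k, x(k-rho1)) w(k)
                 + Lx vx(k)
        y(k+1) = -(C+dC) y(k-rho2) + (D+dD) x(k-tau(k))
                 + (F+dF) sum_n xi_n x(k-n) + Ly vy(k)

    Measurements ``Zx = M x``, ``Zy = N y`` reach the estimator either
    current or one step old, chosen by Bernoulli draws with success
    probabilities ``alpha0``, ``beta0``.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    F: np.ndarray
    H: np.ndarray
    Lx: np.ndarray
    Ly: np.ndarray
    M: np.ndarray
    N: np.ndarray
    rho1: int = 1
    rho2: int = 1
    delta_m: int = 0
    delta_M: int = 0
    tau_m: int = 0
    tau_M: int = 0
    mu_kernel: ExponentialKernel = field(default_factory=lambda: ExponentialKernel(2.0))
    xi_kernel: ExponentialKernel = field(default_factory=lambda: ExponentialKernel(2.0))
    alpha0: float = 1.0
    beta0: float = 1.0
    hill_coeff: float = 2.0
    uncertainty: Optional[UncertaintyStructure] = None
    # printed alongside the worked examples but consumed by no recursion;
    # stored verbatim so fixtures round-trip, never used by the dynamics.
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        for name in ("A", "B", "C", "D", "E", "F", "H", "Lx", "Ly"):
            setattr(self, name, _as_matrix(getattr(self, name), n, n, name))
        self.M = np.asarray(self.M, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.M.ndim != 2 or self.M.shape[1] != n:
            raise ValueError("M must be l x n")
        if self.N.shape != self.M.shape:
            raise ValueError("N must match M's shape")

        for name in ("A", "C"):
            mat = getattr(self, name)
            if not np.allclose(mat, np.diag(np.diag(mat))):
                raise ValueError(f"{name} must be diagonal")
            if np.min(np.diag(mat)) <= 0:
                raise ValueError(f"{name} must have strictly positive diagonal")
        # Translation rates are nonnegative; zero is allowed so that fully
        # decoupled test systems remain constructible.
        if np.min(np.diag(self.D)) < 0:
            raise ValueError("D must have non-negative diagonal")

        _check_symmetric(self.H, "H")
        if np.min(np.linalg.eigvalsh(self.H)) <= 0:
            raise ValueError("H must be symmetric positive definite")

        for name in ("rho1", "rho2", "delta_m", "delta_M", "tau_m", "tau_M"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.delta_m > self.delta_M or self.tau_m > self.tau_M:
            raise ValueError("delay bounds must satisfy m <= M")

        for name in ("alpha0", "beta0"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def l(self) -> int:
        return self.M.shape[0]

    @property
    def mu_bar(self) -> float:
        """Total mass of the mRNA-channel distributed-delay kernel."""
        return self.mu_kernel.total_mass

    @property
    def xi_bar(self) -> float:
        return self.xi_kernel.total_mass

    @property
    def sigma_alpha(self) -> float:
        """Variance of the Bernoulli dropout draw for the x measurement."""
        return self.alpha0 * (1.0 - self.alpha0)

    @property
    def sigma_beta(self) -> float:
        return self.beta0 * (1.0 - self.beta0)

    def activation(self, s):
        """Hill regulation applied to a state vector.

        The dynamics can drive states below zero, where the Hill form is
        not defined; negative concentrations exert no transcriptional
        activation, so the input is clipped at zero.  The clipped function
        is monotone nondecreasing on all of R with slopes inside the same
        [0, max-slope] sector as the Hill curve itself.
        """
        return hill_activation(np.clip(s, 0.0, None), self.hill_coeff)

    def without_uncertainty(self) -> "GRNModel":
        import copy

        m = copy.copy(self)
        m.uncertainty = None
        return m


@dataclass(frozen=True)
class EstimatorGains:
    """The four Luenberger-style gain matrices of the linear estimator.

    ``xhat(k+1) = -Ax xhat(k) + Bx Zx_tilde(k)`` and the y analogue.
    """

    Ax: np.ndarray
    Ay: np.ndarray
    Bx: np.ndarray
    By: np.ndarray

    def __post_init__(self) -> None:
        for name in ("Ax", "Ay", "Bx", "By"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        n = self.Ax.shape[0]
        if self.Ax.shape != (n, n) or self.Ay.shape != (n, n):
            raise ValueError("Ax, Ay must be square n x n")
        if self.Bx.shape[0] != n or self.By.shape[0] != n:
            raise ValueError("Bx, By must have n rows")

    @classmethod
    def zero(cls, n: int, l: Optional[int] = None) -> "EstimatorGains":
        l = n if l is None else l
        z, zl = np.zeros((n, n)), np.zeros((n, l))
        return cls(Ax=z, Ay=z.copy(), Bx=zl, By=zl.copy())


@dataclass
class StabilityVerdict:
    """Outcome of a Monte-Carlo stability / attenuation check.

    ``decay_factor`` is the fitted geometric rate mu of the ensemble
    mean-square error (valid when the log-linear fit is tight), ``prefactor``
    the fitted constant alpha, ``hinf_ratio`` the worst observed
    output-to-disturbance energy ratio, compared against ``gamma**2``.
    """

    stable: Optional[bool] = None
    decay_factor: Optional[float] = None
    prefactor: Optional[float] = None
    fit_r2: Optional[float] = None
    mu_upper: Optional[float] = None
    hinf_ratio: Optional[float] = None
    gamma: Optional[float] = None
    hinf_holds: Optional[bool] = None
    inconclusive: bool = False
    per_mode: dict = field(default_factory=dict)
    notes: str = ""
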
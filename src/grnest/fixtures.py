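"""Packaged parameter sets for the two worked examples, plus a seeded
random stable-model generator for property tests.

The first worked example prints two parameter sets (the system set and the
estimation-error-system set); both are exposed as variants ``4.1a`` and
``4.1b`` because the source does not say which one fed the reported solver
run.  Matrices printed in the source are stored verbatim; quantities the
source omits (noise bound H, measurement matrices in variant a, dropout
probabilities in variant a, the kernel family behind the scalar mu = xi
printings) get documented package defaults.  The printed ``d1``, ``d2``,
``G`` have no consumer in the dynamics and are kept in ``extras``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    EstimatorGains,
    ExponentialKernel,
    GRNModel,
    SectorBounds,
    UncertaintyStructure,
)
from .simulator import DelaySchedule, default_disturbances

__all__ = [
    "example_4_1",
    "example_4_2",
    "random_stable_model",
    "ExampleFixture",
]

# defaults for quantities the worked examples do not print
_H_DEFAULT_SCALE = 0.01
_ALPHA0_DEFAULT = 0.9
_BETA0_DEFAULT = 0.9


@dataclass
class ExampleFixture:
    model: GRNModel
    schedule: DelaySchedule
    sector: SectorBounds
    gains: EstimatorGains | None
    disturbances: callable
    printed_solution: dict | None = None


def _trig_schedule() -> DelaySchedule:
    # delta(k) = 3 + 2 sin(k pi/2), tau(k) = 3 + 2 cos(k pi/2):
    # integer-valued at integer k, ranging over {1, 3, 5}
    return DelaySchedule(
        delta=lambda k: 3.0 + 2.0 * math.sin(k * math.pi / 2.0),
        tau=lambda k: 3.0 + 2.0 * math.cos(k * math.pi / 2.0),
    )


def example_4_1(variant: str = "4.1a") -> ExampleFixture:
    """Two-gene example with trigonometric delays and sin/cos uncertainty.

    ``variant='4.1a'`` is the system parameter set, ``'4.1b'`` the
    estimation-error-system set (which also prints measurement matrices,
    dropout probabilities, and the candidate estimator gains).
    """
    I2 = np.eye(2)
    sector = SectorBounds.for_hill(2, h=2.0)
    if variant == "4.1a":
        model = GRNModel(
            A=np.diag([0.1, 0.2]),
            B=np.diag([0.08, 0.2]),
            C=np.diag([0.1, 0.1]),
            D=np.diag([0.1, 0.1]),
            E=np.diag([0.36, 0.1]),
            F=0.4 * I2,
            H=_H_DEFAULT_SCALE * I2,
            Lx=np.diag([0.2, 0.5]),
            Ly=np.diag([0.5, 0.2]),
            M=I2.copy(),
            N=I2.copy(),
            rho1=1,
            rho2=1,
            delta_m=1, delta_M=5, tau_m=1, tau_M=5,
            mu_kernel=ExponentialKernel(2.0),
            xi_kernel=ExponentialKernel(2.0),
            alpha0=_ALPHA0_DEFAULT,
            beta0=_BETA0_DEFAULT,
            hill_coeff=2.0,
            uncertainty=UncertaintyStructure(
                R=0.2 * I2, **{f"W{i}": 0.3 * I2 for i in range(1, 7)}
            ),
            extras={
                "d1": [[0.1, 0.0], [0.0, 0.1]],
                "d2": [[0.28, 0.0], [0.0, 0.135]],
                "G": "diag(sin(k), cos(k))",
            },
        )
        return ExampleFixture(
            model=model,
            schedule=_trig_schedule(),
            sector=sector,
            gains=None,
            disturbances=lambda K: default_disturbances(K, 2, "4.1a"),
        )
    if variant == "4.1b":
        model = GRNModel(
            A=0.1 * I2,
            B=np.array([[-0.1, 0.0], [0.0, 0.2]]),
            C=0.2 * I2,
            D=0.2 * I2,
            E=0.3 * I2,
            F=0.3 * I2,
            H=_H_DEFAULT_SCALE * I2,
            Lx=np.diag([0.5, 0.2]),
            Ly=np.diag([0.1, 0.1]),
            M=np.array([[0.6, 0.0], [0.0, 0.1]]),
            N=np.array([[0.4, 0.0], [0.3, 0.5]]),
            rho1=1,
            rho2=1,
            delta_m=1, delta_M=5, tau_m=1, tau_M=5,
            mu_kernel=ExponentialKernel(1.0),
            xi_kernel=ExponentialKernel(1.0),
            alpha0=0.001,
            beta0=0.003,
            hill_coeff=2.0,
            uncertainty=UncertaintyStructure(
                R=np.diag([0.1, 0.3]), **{f"W{i}": 0.1 * I2 for i in range(1, 7)}
            ),
            extras={
                # d1 entries printed as 0.2(cos(pi/2)-2), 0.1(sin(pi/2)-1)
                "d1": [[0.2 * (math.cos(math.pi / 2) - 2), 0.0],
                       [0.0, 0.1 * (math.sin(math.pi / 2) - 1)]],
                "d2": [[0.28, 0.0], [0.0, 0.135]],
                "N_of_k": "diag(sin(k pi/2), cos(k pi/2))",
            },
        )
        gains = EstimatorGains(
            Ax=np.array([[1.2173, 0.4060], [0.6324, 0.1804]]),
            Ay=np.array([[0.2203, 0.0032], [0.0063, 0.2096]]),
            Bx=np.array([[2.1102, 0.4831], [1.3729, 0.3185]]),
            By=np.array([[0.2005, 0.4226], [0.8342, 0.3887]]),
        )
        printed = {
            "X1": np.array([[0.4338, -0.0041], [-0.0041, 0.2852]]),
            "X2": np.array([[0.0210, -0.0260], [-0.0260, 0.0533]]),
            "R11": np.array([[9.3434, 0.0025], [0.0025, 6.9265]]),
            "R21": np.array([[0.2169, -0.4861], [-0.4861, 0.9363]]),
            "Y1": np.array([[1.1918, -0.0128], [-0.0128, 0.5832]]),
            "Y2": np.array([[1.0836, -0.2279], [-0.2279, 0.1073]]),
        }
        return ExampleFixture(
            model=model,
            schedule=_trig_schedule(),
            sector=sector,
            gains=gains,
            disturbances=lambda K: default_disturbances(K, 2, "4.1b"),
            printed_solution=printed,
        )
    raise ValueError(f"unknown variant {variant!r}; use '4.1a' or '4.1b'")


def example_4_2() -> ExampleFixture:
    """Second worked example: constant delays, no parameter uncertainty."""
    I2 = np.eye(2)
    model = GRNModel(
        A=np.diag([0.3, 0.2]),
        B=np.array([[-0.5, 0.0], [2.5, 0.0]]),
        C=np.diag([0.1, 0.2]),
        D=np.diag([0.08, 0.2]),
        E=np.diag([0.36, 0.1]),
        F=np.diag([0.4, 0.4]),
        H=_H_DEFAULT_SCALE * I2,
        Lx=np.diag([0.3, 0.4]),
        Ly=np.diag([0.5, 0.2]),
        M=I2.copy(),
        N=I2.copy(),
        rho1=1,
        rho2=1,
        delta_m=2, delta_M=2, tau_m=1, tau_M=1,
        mu_kernel=ExponentialKernel(2.0),
        xi_kernel=ExponentialKernel(2.0),
        alpha0=_ALPHA0_DEFAULT,
        beta0=_BETA0_DEFAULT,
        hill_coeff=2.0,
        uncertainty=None,
        extras={
            "d1": [[0.6, 0.0], [0.0, 0.1]],
            "d2": [[0.28, 0.0], [0.0, 0.135]],
        },
    )
    return ExampleFixture(
        model=model,
        schedule=DelaySchedule.constant(delta=2, tau=1),
        sector=SectorBounds.for_hill(2, h=2.0),
        gains=None,
        disturbances=lambda K: default_disturbances(K, 2, "4.2"),
    )


def random_stable_model(
    seed: int,
    n: int = 2,
    target_contraction: float = 0.3,
    with_uncertainty: bool = True,
) -> GRNModel:
    """A seeded random model whose delay-free linearization is a contraction.

    Degradation rates are drawn inside (0, target); the coupling and
    distributed-delay weight matrices are rescaled so the worst-case linear
    gain matrix (activation replaced by its maximal slope) has spectral
    radius at most the target.  The noise bound is a small random SPD
    matrix; a light norm-bounded uncertainty structure is attached by
    default so robustness sweeps exercise a nontrivial perturbation.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0.0 < target_contraction < 1.0):
        raise ValueError("target_contraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    t = target_contraction
    A = np.diag(rng.uniform(0.3 * t, 0.9 * t, n))
    C = np.diag(rng.uniform(0.3 * t, 0.9 * t, n))
    D = np.diag(rng.uniform(0.1 * t, 0.5 * t, n))
    B = rng.uniform(-1.0, 1.0, (n, n))
    E = rng.uniform(-1.0, 1.0, (n, n))
    F = rng.uniform(-1.0, 1.0, (n, n))
    mu_k = ExponentialKernel(2.0)
    xi_k = ExponentialKernel(2.0)
    slope = 3.0 * np.sqrt(3.0) / 8.0       # max Hill slope for h = 2
    for _ in range(60):
        gain = np.block(
            [
                [np.abs(A), slope * (np.abs(B) + mu_k.total_mass * np.abs(E))],
                [np.abs(D) + xi_k.total_mass * np.abs(F), np.abs(C)],
            ]
        )
        rho = float(np.max(np.abs(np.linalg.eigvals(gain))))
        if rho <= t:
            break
        shrink = 0.8 * t / rho
        B, E, F = B * shrink, E * shrink, F * shrink
    G = rng.standard_normal((n, n)) * 0.05
    H = G @ G.T + 0.005 * np.eye(n)
    unc = None
    if with_uncertainty:
        unc = UncertaintyStructure(
            R=0.05 * np.eye(n), **{f"W{i}": 0.05 * np.eye(n) for i in range(1, 7)}
        )
    return GRNModel(
        A=A, B=B, C=C, D=D, E=E, F=F, H=H,
        Lx=0.2 * np.eye(n), Ly=0.2 * np.eye(n),
        M=np.eye(n), N=np.eye(n),
        rho1=1, rho2=1,
        delta_m=0, delta_M=2, tau_m=0, tau_M=2,
        mu_kernel=mu_k, xi_kernel=xi_k,
        alpha0=0.9, beta0=0.9,
        hill_coeff=2.0,
        uncertainty=unc,
    )
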
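"""Dense spectral solver for small LMI feasibility problems.

A linear matrix inequality system asks for a decision vector theta with

    F_j(theta) < 0   for every constraint block j,

where each ``F_j`` is symmetric and affine in theta.  For the block sizes
arising here (well under 100 x 100, a few dozen decision scalars) the
feasibility problem is solved directly as unconstrained convex minimization
of the worst eigenvalue,

    f(theta) = max_j lambda_max(F_j(theta)),

which is convex but nonsmooth.  We minimize an annealed log-sum-exp
smoothing of f (smooth, convex, gradient available in closed form from the
eigenvectors) with L-BFGS-B under box bounds, tightening the temperature in
stages and warm-starting each stage at the previous solution.  A strictly
negative final value certifies feasibility; the achieved value is the
feasibility margin.

The affine structure is extracted exactly by evaluating the assembly
callback at the origin and at unit coordinate vectors -- valid because the
family is affine, and itself checked by :func:`check_affine`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = ["AffineBlock", "extract_affine", "check_affine", "SpectralSolver"]


@dataclass
class AffineBlock:
    """One symmetric constraint block ``F(theta) = A0 + sum_i theta_i A_i``."""

    name: str
    A0: np.ndarray          # (d, d)
    A: np.ndarray           # (nvar, d, d)

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return self.A0 + np.tensordot(theta, self.A, axes=1)

    @property
    def dim(self) -> int:
        return self.A0.shape[0]


def extract_affine(
    fn: Callable[[np.ndarray], np.ndarray], nvar: int, name: str = "block"
) -> AffineBlock:
    """Exact affine representation of ``fn`` (must be affine in theta)."""
    A0 = np.asarray(fn(np.zeros(nvar)), dtype=float)
    d = A0.shape[0]
    A = np.empty((nvar, d, d))
    e = np.zeros(nvar)
    for i in range(nvar):
        e[i] = 1.0
        A[i] = np.asarray(fn(e), dtype=float) - A0
        e[i] = 0.0
    return AffineBlock(name=name, A0=A0, A=A)


def check_affine(
    fn: Callable[[np.ndarray], np.ndarray],
    block: AffineBlock,
    rng: np.random.Generator,
    n_points: int = 2,
    tol: float = 1e-8,
) -> float:
    """Max reconstruction error of the affine model at random points."""
    worst = 0.0
    for _ in range(n_points):
        theta = rng.standard_normal(block.A.shape[0])
        err = float(np.max(np.abs(fn(theta) - block(theta))))
        worst = max(worst, err)
    if worst > tol:
        raise AssertionError(f"{block.name} is not affine (error {worst:.2e})")
    return worst


class SpectralSolver:
    """Feasibility via smoothed worst-eigenvalue minimization."""

    def __init__(
        self,
        blocks: Sequence[AffineBlock],
        lower: np.ndarray,
        upper: np.ndarray,
    ):
        self.blocks = list(blocks)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.nvar = self.lower.shape[0]

    # -- objective -----------------------------------------------------

    def worst_eig(self, theta: np.ndarray) -> float:
        return max(
            float(np.linalg.eigvalsh(b(theta))[-1]) for b in self.blocks
        )

    def margins(self, theta: np.ndarray) -> dict[str, float]:
        """Per-block feasibility margin: -lambda_max(F_j(theta))."""
        return {
            b.name: -float(np.linalg.eigvalsh(b(theta))[-1]) for b in self.blocks
        }

    def _smoothed(self, theta: np.ndarray, t: float):
        """log-sum-exp smoothing of the pooled eigenvalues + gradient."""
        eigs_all = []
        decomps = []
        for b in self.blocks:
            w, V = np.linalg.eigh(b(theta))
            eigs_all.append(w)
            decomps.append((b, w, V))
        pooled = np.concatenate(eigs_all)
        m = float(pooled.max())
        z = np.exp((pooled - m) / t)
        Z = float(z.sum())
        f = m + t * np.log(Z)
        grad = np.zeros(self.nvar)
        for b, w, V in decomps:
            wz = np.exp((w - m) / t) / Z
            # weight matrix  W = V diag(wz) V';  d f / d theta_i = <A_i, W>
            Wmat = (V * wz) @ V.T
            grad += np.tensordot(b.A, Wmat, axes=([1, 2], [0, 1]))
        return f, grad

    # -- driver --------------------------------------------------------

    def solve(
        self,
        x0: Optional[np.ndarray] = None,
        temperatures: Sequence[float] = (1.0, 0.1, 0.01, 1e-3, 1e-4),
        maxiter: int = 400,
        restarts: int = 2,
        seed: int = 0,
    ) -> tuple[np.ndarray, float]:
        """Return ``(theta, worst_eig)`` over annealed stages and restarts."""
        rng = np.random.default_rng(seed)
        best_theta, best_val = None, np.inf
        base = (
            np.clip(np.asarray(x0, float), self.lower, self.upper)
            if x0 is not None
            else np.clip(np.zeros(self.nvar), self.lower, self.upper)
        )
        starts = [base]
        for _ in range(restarts):
            pert = base + rng.standard_normal(self.nvar) * 0.3 * (1 + np.abs(base))
            starts.append(np.clip(pert, self.lower, self.upper))
        bounds = list(zip(self.lower, self.upper))
        for start in starts:
            theta = start.copy()
            for t in temperatures:
                res = minimize(
                    self._smoothed,
                    theta,
                    args=(t,),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-12},
                )
                theta = res.x
            val = self.worst_eig(theta)
            if val < best_val:
                best_theta, best_val = theta, val
            if best_val < 0:
                break
        return best_theta, best_val
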
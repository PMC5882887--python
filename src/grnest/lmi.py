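"""Assembly and solution of the delay-dependent stability LMIs.

Four block LMI systems are assembled over the decision variables
``R11..R52`` (symmetric positive definite), the S-procedure multiplier
``lambda``, the uncertainty-bound scalars ``eps1``, ``eps2``, the
attenuation level ``gamma**2``, and -- in synthesis mode -- the
change-of-variable matrices ``X1 = R21 Ax``, ``X2 = R21 Bx``,
``Y1 = R22 Ay``, ``Y2 = R22 By`` from which the estimator gains are
recovered by linear solves.

Every problem is exposed in two fidelities:

* ``paper-faithful`` places every printed block with its printed sign.  As
  printed, several diagonal blocks (``H R11``, ``I(R12+R22)``,
  ``I(R11+R21)``, ``+mu_bar R51``, and a zero block at the y-channel
  leakage coordinate) are forced positive semidefinite whenever the
  R-matrices are positive definite, so the strict inequality can never
  hold; :func:`solve` certifies this analytically without calling the
  numerical backend.
* ``repaired`` is the completed derivation: leakage-window matrices Q1, Q2
  supply the missing negative mass at the leakage coordinates, a second
  sector multiplier lam2 dominates the positive ``mu_bar R51`` block, the
  distributed-delay aggregates receive the series inequality's actual
  yield ``-(1/xi_bar) R52`` / ``-(1/mu_bar) R51``, the attenuation form
  gains its disturbance couplings (``sqrt2 (R11+R21) Lx`` etc.) and +I
  output blocks, and the ``eps Wbar' Wbar`` uncertainty-bound terms land
  on the coordinates the perturbation factors actually touch.  This
  reading admits feasible solutions and is the one used for gain
  synthesis; it is an interpretation, applied only when requested, and
  its certificates are cross-checked by Monte-Carlo in ``grnest.verify``.
  Details and rationale: docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import EstimatorGains, GRNModel, SectorBounds
from .sdp import SpectralSolver, extract_affine

__all__ = [
    "LMIProblem",
    "SynthesisResult",
    "VariableLayout",
    "assemble_analysis",
    "assemble_hinf",
    "assemble_synthesis",
    "assemble_nominal",
    "solve",
    "recover_gains",
    "minimize_gamma",
    "schur_equivalence",
    "series_inequality_slack",
]


# --------------------------------------------------------------------------
# variable layout
# --------------------------------------------------------------------------

_R_NAMES = ("R11", "R12", "R21", "R22", "R31", "R32", "R41", "R42", "R51", "R52")


def _vech_indices(n: int):
    return np.triu_indices(n)


def _sym_from_vech(v: np.ndarray, n: int) -> np.ndarray:
    iu = _vech_indices(n)
    m = np.zeros((n, n))
    m[iu] = v
    m = m + m.T - np.diag(np.diag(m))
    return m


@dataclass
class VariableLayout:
    """Order and packing of the decision variables into a flat vector."""

    entries: list  # (name, kind, shape) with kind in {"sym", "full", "scalar"}

    @property
    def size(self) -> int:
        total = 0
        for _, kind, shape in self.entries:
            if kind == "sym":
                n = shape[0]
                total += n * (n + 1) // 2
            elif kind == "full":
                total += shape[0] * shape[1]
            else:
                total += 1
        return total

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        i = 0
        for name, kind, shape in self.entries:
            if kind == "sym":
                n = shape[0]
                m = n * (n + 1) // 2
                out[name] = _sym_from_vech(theta[i : i + m], n)
                i += m
            elif kind == "full":
                r, c = shape
                out[name] = theta[i : i + r * c].reshape(r, c)
                i += r * c
            else:
                out[name] = float(theta[i])
                i += 1
        return out

    def pack(self, values: dict) -> np.ndarray:
        theta = np.zeros(self.size)
        i = 0
        for name, kind, shape in self.entries:
            v = values[name]
            if kind == "sym":
                n = shape[0]
                m = n * (n + 1) // 2
                theta[i : i + m] = np.asarray(v)[_vech_indices(n)]
                i += m
            elif kind == "full":
                r, c = shape
                theta[i : i + r * c] = np.asarray(v).ravel()
                i += r * c
            else:
                theta[i] = float(v)
                i += 1
        return theta


# --------------------------------------------------------------------------
# block assembly
# --------------------------------------------------------------------------


def _zeros_grid(rows, cols, n):
    return [[np.zeros((n, n)) for _ in range(cols)] for _ in range(rows)]


def _sym(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def _uncertainty_factors(model: GRNModel):
    n = model.n
    z = np.zeros((n, n))
    if model.uncertainty is None:
        return z, (z,) * 6
    u = model.uncertainty
    return u.R, u.W

def _lambda11_grid(v, model: GRNModel, fidelity: str, hinf_output: bool = False):
    """Diagonal blocks of the 7n x 7n upper-left matrix of the x channel.

    Coordinates: x(k), xerr(k), x(k-1), x(k-tau(k)), x(k-rho1),
    sum xi_n x(k-n), and the second distributed-delay aggregate.

    Paper-faithful places every printed block with its printed sign (which
    leaves the leakage coordinate with the positive noise-energy block
    ``sym(H R11)`` and nothing negative).  The repaired reading completes
    the derivation: a leakage-window matrix Q1 enters psi11 positively and
    the leakage diagonal negatively, the distributed-delay aggregate gets
    the series inequality's actual yield ``-(1/xi_bar) R52``, and the
    uncertainty-bound term ``eps1 Wbar1' Wbar1`` lands on the coordinates
    the perturbation factors touch.  ``hinf_output`` adds the +I output
    blocks of the attenuation functional at the (state, error) coordinates.
    """
    n = model.n
    _, W = _uncertainty_factors(model)
    W1, _, _, W4, _, W6 = W
    xi_bar = model.xi_bar
    g = _zeros_grid(7, 7, n)
    psi11 = (
        -v["R11"] + v["R31"] + (model.tau_M - model.tau_m + 1) * v["R41"]
        + xi_bar * v["R52"]
    )
    g[1][1] = -v["R21"]
    g[2][2] = -v["R31"]
    g[3][3] = -v["R41"] + v["eps1"] * (W4.T @ W4)
    g[6][6] = -xi_bar * v["R52"]
    if fidelity == "paper-faithful":
        g[0][0] = psi11
        g[4][4] = _sym(model.H @ v["R11"])
        g[5][5] = v["R12"] + v["R22"]
    else:
        g[0][0] = psi11 + v["Q1"]
        g[4][4] = (
            _sym(model.H @ (v["R11"] + v["R21"])) - v["Q1"]
            + v["eps1"] * (W1.T @ W1)
        )
        g[5][5] = -(1.0 / xi_bar) * v["R52"] + v["eps1"] * (W6.T @ W6)
        if hinf_output:
            g[0][0] = g[0][0] + np.eye(n)
            g[1][1] = g[1][1] + np.eye(n)
    return g


def _lambda22_grid(
    v, model: GRNModel, sector: SectorBounds, fidelity: str,
    hinf_output: bool = False,
):
    """Diagonal + sector blocks of the 9n x 9n upper-left y-channel matrix.

    Coordinates: y(k), yerr(k), y(k-1), y(k-delta(k)), g(y(k-delta)),
    y(k-rho2), sum mu_s h(y(k-s)), h(y(k)), second aggregate.

    Repaired reading: leakage-window matrix Q2 (the printed zero block at
    y(k-rho2) rules out strict definiteness otherwise), a second sector
    multiplier lam2 coupling h(y(k)) back to y(k) so the positive
    ``mu_bar R51`` mass can be dominated, and the kernel-mass block
    ``-(1/mu_bar) R51`` at the aggregate the E-coupling actually touches.
    """
    n = model.n
    _, W = _uncertainty_factors(model)
    _, W2, W3, _, W5, _ = W
    mu_bar = model.mu_bar
    lam = v["lam"]
    Nt1, Nt2 = sector.Ntilde1, sector.Ntilde2
    g = _zeros_grid(9, 9, n)
    psi12 = (
        -v["R12"] + v["R32"] + (model.delta_M - model.delta_m + 1) * v["R42"]
    )
    g[1][1] = -v["R22"]
    g[2][2] = -v["R32"]
    g[3][3] = -v["R42"] - lam * Nt1
    g[3][4] = -lam * Nt2.T
    g[4][3] = -lam * Nt2
    g[4][4] = -lam * np.eye(n)
    g[8][8] = -mu_bar * v["R51"]
    if fidelity == "paper-faithful":
        g[0][0] = psi12
        g[3][3] = g[3][3] + v["eps2"] * (W2.T @ W2)   # printed placement
        g[6][6] = v["R11"] + v["R21"]
        g[7][7] = mu_bar * v["R51"]
    else:
        lam2 = v["lam2"]
        g[0][0] = psi12 + v["Q2"] - lam2 * Nt1
        g[0][7] = -lam2 * Nt2.T
        g[7][0] = -lam2 * Nt2
        g[4][4] = g[4][4] + v["eps2"] * (W2.T @ W2)   # coordinate W2 acts on
        g[5][5] = -v["Q2"] + v["eps2"] * (W3.T @ W3)
        g[6][6] = -(1.0 / mu_bar) * v["R51"] + v["eps2"] * (W5.T @ W5)
        g[7][7] = mu_bar * v["R51"] - lam2 * np.eye(n)
        if hinf_output:
            g[0][0] = g[0][0] + np.eye(n)
            g[1][1] = g[1][1] + np.eye(n)
    return g


def _s1_grid(v, model: GRNModel, gains: Optional[EstimatorGains], synthesis: bool):
    """5n x 7n coupling rows of the x channel (Schur-complement block)."""
    n = model.n
    r2 = np.sqrt(2.0)
    sa = np.sqrt(model.sigma_alpha)
    R1121 = v["R11"] + v["R21"]
    R1222 = v["R12"] + v["R22"]
    g = _zeros_grid(5, 7, n)
    g[0][4] = -r2 * (R1121 @ model.A)
    if synthesis:
        X1, X2M = v["X1"], v["X2"] @ model.M
        g[1][0] = r2 * (X1 - model.alpha0 * X2M)
        g[1][1] = -r2 * X1
        g[1][2] = -r2 * (1.0 - model.alpha0) * X2M
        g[2][0] = sa * X2M
        g[2][2] = sa * X2M
    else:
        R21 = v["R21"]
        BxM = gains.Bx @ model.M
        g[1][0] = r2 * (R21 @ (gains.Ax - model.alpha0 * BxM))
        g[1][1] = -r2 * (R21 @ gains.Ax)
        g[1][2] = -r2 * (1.0 - model.alpha0) * (R21 @ BxM)
        g[2][0] = sa * (R21 @ BxM)
        g[2][2] = sa * (R21 @ BxM)
    g[3][3] = r2 * (R1222 @ model.D)
    g[4][5] = r2 * (R1222 @ model.F)
    return g


def _s2_grid(v, model: GRNModel, gains: Optional[EstimatorGains], synthesis: bool):
    n = model.n
    r2 = np.sqrt(2.0)
    sb = np.sqrt(model.sigma_beta)
    R1121 = v["R11"] + v["R21"]
    R1222 = v["R12"] + v["R22"]
    g = _zeros_grid(5, 9, n)
    g[0][5] = -r2 * (R1222 @ model.C)
    if synthesis:
        Y1, Y2N = v["Y1"], v["Y2"] @ model.N
        g[1][0] = r2 * (Y1 - model.beta0 * Y2N)
        g[1][1] = -r2 * Y1
        g[1][2] = -r2 * (1.0 - model.beta0) * Y2N
        g[2][0] = sb * Y2N
        g[2][2] = sb * Y2N
    else:
        R22 = v["R22"]
        ByN = gains.By @ model.N
        g[1][0] = r2 * (R22 @ (gains.Ay - model.beta0 * ByN))
        g[1][1] = -r2 * (R22 @ gains.Ay)
        g[1][2] = -r2 * (1.0 - model.beta0) * (R22 @ ByN)
        g[2][0] = sb * (R22 @ ByN)
        g[2][2] = sb * (R22 @ ByN)
    g[3][4] = r2 * (R1121 @ model.B)
    g[4][6] = r2 * (R1121 @ model.E)
    return g


def _j1(v, n):
    R1121, R1222 = v["R11"] + v["R21"], v["R12"] + v["R22"]
    return [-R1121, -v["R21"], -v["R21"], -R1222, -R1222]


def _j2(v, n):
    R1121, R1222 = v["R11"] + v["R21"], v["R12"] + v["R22"]
    return [-R1222, -v["R22"], -v["R22"], -R1121, -R1121]


def _t1_grid(v, model: GRNModel):
    n = model.n
    T, _ = _uncertainty_factors(model)
    r2 = np.sqrt(2.0)
    R1121, R1222 = v["R11"] + v["R21"], v["R12"] + v["R22"]
    g = _zeros_grid(5, 7, n)
    g[0][4] = -r2 * (R1121 @ T)
    g[3][3] = r2 * (R1222 @ T)
    g[4][5] = r2 * (R1222 @ T)
    return g


def _t2_grid(v, model: GRNModel):
    n = model.n
    T, _ = _uncertainty_factors(model)
    r2 = np.sqrt(2.0)
    R1121, R1222 = v["R11"] + v["R21"], v["R12"] + v["R22"]
    g = _zeros_grid(5, 9, n)
    g[0][5] = -r2 * (R1222 @ T)
    g[3][4] = r2 * (R1121 @ T)
    g[4][6] = r2 * (R1121 @ T)
    return g


def _grid_to_mat(g):
    return np.block(g)


def _compose(L, S, Jdiag, Tg, mode, n, eps_name, v, gamma2, fidelity, vcol=None):
    """Stack the block rows of one full LMI matrix for the given mode.

    ``vcol`` is the disturbance coupling column of the S-rows (repaired
    attenuation forms only; the printed form leaves it zero).
    """
    Lm = _grid_to_mat(L)
    Sm = _grid_to_mat(S)
    Tm = _grid_to_mat(Tg)
    p = Lm.shape[0]          # 7n or 9n
    q = Sm.shape[0]          # 5n
    Jm = np.zeros((q, q))
    for i, blk in enumerate(Jdiag):
        Jm[i * n : (i + 1) * n, i * n : (i + 1) * n] = blk
    if mode == "analysis":
        eps = v[eps_name]
        top = np.hstack([Lm, Sm.T, np.zeros((p, p))])
        mid = np.hstack([Sm, Jm, Tm])
        bot = np.hstack([np.zeros((p, p)), Tm.T, -eps * np.eye(p)])
        return np.vstack([top, mid, bot])
    if mode in ("hinf", "synthesis"):
        eps = v[eps_name]
        zpn = np.zeros((p, n))
        Vc = np.zeros((q, n)) if vcol is None else vcol
        r1 = np.hstack([Lm, zpn, Sm.T, np.zeros((p, p))])
        r2 = np.hstack([zpn.T, -gamma2 * np.eye(n), Vc.T, np.zeros((n, p))])
        r3 = np.hstack([Sm, Vc, Jm, Tm])
        r4 = np.hstack([np.zeros((p, p)), np.zeros((p, n)), Tm.T, -eps * np.eye(p)])
        return np.vstack([r1, r2, r3, r4])
    if mode == "nominal":
        c = 1.0 if fidelity == "paper-faithful" else -1.0
        top = np.hstack([Lm, Sm.T, np.zeros((p, p))])
        mid = np.hstack([Sm, Jm, np.zeros((q, p))])
        bot = np.hstack([np.zeros((p, p)), np.zeros((p, q)), c * np.eye(p)])
        return np.vstack([top, mid, bot])
    raise ValueError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# problem container
# --------------------------------------------------------------------------


@dataclass
class LMIProblem:
    """An assembled LMI system with its decision-variable layout.

    ``assemble(values)`` returns the pair of full symmetric matrices that
    must be negative definite.  ``gamma`` fixed (float) or None (gamma**2 is
    then itself a decision variable, enabling attenuation minimization).
    """

    mode: str                       # analysis | hinf | synthesis | nominal
    fidelity: str                   # paper-faithful | repaired
    model: GRNModel
    sector: SectorBounds
    gains: Optional[EstimatorGains]
    gamma: Optional[float]
    layout: VariableLayout

    def __post_init__(self) -> None:
        if self.fidelity not in ("paper-faithful", "repaired"):
            raise ValueError("fidelity must be 'paper-faithful' or 'repaired'")

    @property
    def n(self) -> int:
        return self.model.n

    @property
    def synthesis(self) -> bool:
        return self.mode == "synthesis"

    def dims(self) -> tuple[int, int]:
        n = self.n
        if self.mode in ("analysis", "nominal"):
            return 19 * n, 23 * n
        return 20 * n, 24 * n

    def assemble(self, values: dict) -> tuple[np.ndarray, np.ndarray]:
        v = dict(values)
        v.setdefault("eps1", 1.0)
        v.setdefault("eps2", 1.0)
        if self.fidelity == "repaired":
            v.setdefault("Q1", np.eye(self.n))
            v.setdefault("Q2", np.eye(self.n))
            v.setdefault("lam2", 1.0)
        if self.gamma is not None:
            gamma2 = self.gamma**2
        else:
            gamma2 = v.get("gamma2", 1.0)
        n = self.n
        attenuating = self.mode in ("hinf", "synthesis")
        hout = attenuating and self.fidelity == "repaired"
        L11 = _lambda11_grid(v, self.model, self.fidelity, hinf_output=hout)
        L22 = _lambda22_grid(v, self.model, self.sector, self.fidelity,
                             hinf_output=hout)
        S1 = _s1_grid(v, self.model, self.gains, self.synthesis)
        S2 = _s2_grid(v, self.model, self.gains, self.synthesis)
        v1col = v2col = None
        if hout:
            r2 = np.sqrt(2.0)
            v1col = np.zeros((5 * n, n))
            v1col[:n] = r2 * ((v["R11"] + v["R21"]) @ self.model.Lx)
            v2col = np.zeros((5 * n, n))
            v2col[:n] = r2 * ((v["R12"] + v["R22"]) @ self.model.Ly)
        L1 = _compose(
            L11, S1, _j1(v, n), _t1_grid(v, self.model),
            "hinf" if self.mode == "synthesis" else self.mode,
            n, "eps1", v, gamma2, self.fidelity, vcol=v1col,
        )
        L2 = _compose(
            L22, S2, _j2(v, n), _t2_grid(v, self.model),
            "hinf" if self.mode == "synthesis" else self.mode,
            n, "eps2", v, gamma2, self.fidelity, vcol=v2col,
        )
        return L1, L2

    def assemble_theta(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.assemble(self.layout.unpack(theta))

    # -- diagnosis ------------------------------------------------------

    def _probe_assignments(self, rng_seed: int = 0):
        """Structured + random variable assignments covering the admissible
        cone: each probe is a valid (PD matrices, positive scalars) point."""
        n = self.n
        rng = np.random.default_rng(rng_seed)
        probes = []
        scalar_settings = [
            dict(lam=1e-6, eps1=1e-6, eps2=1e-6, lam2=1e-6),
            dict(lam=10.0, eps1=10.0, eps2=10.0, lam2=10.0),
            dict(lam=10.0, eps1=1e-6, eps2=1e-6, lam2=10.0),
        ]
        var_names = list(_R_NAMES) + ["Q1", "Q2"]
        for big in var_names:
            for sc in scalar_settings:
                v = {name: 0.01 * np.eye(n) for name in var_names}
                v[big] = 100.0 * np.eye(n)
                v.update(sc)
                probes.append(v)
        for _ in range(8):
            v = {}
            for name in var_names:
                a = rng.standard_normal((n, n))
                v[name] = a @ a.T + 0.01 * np.eye(n)
            v.update(
                lam=float(rng.uniform(1e-4, 10)),
                eps1=float(rng.uniform(1e-4, 10)),
                eps2=float(rng.uniform(1e-4, 10)),
                lam2=float(rng.uniform(1e-4, 10)),
            )
            probes.append(v)
        return probes

    def forced_positive_diagonal(self, rng_seed: int = 0) -> Optional[str]:
        """Name a diagonal block that the PD constraints force to be >= 0.

        Scans the named upper-left diagonal blocks over a family of probe
        assignments spanning the admissible cone (each R-matrix pushed
        large in turn, scalars at both extremes, plus random PD draws).  A
        block whose smallest eigenvalue never drops below -1e-9 across all
        probes cannot be made negative definite -- strict negative
        definiteness of the full matrix then fails on the corresponding
        coordinate, an analytic infeasibility certificate that needs no
        solver run.  Blocks that can be made negative are negative at one
        of the structured probes by construction.
        """
        labels11 = [
            "psi11", "-R21", "-R31", "-R41+eps1*W4'W4", "H*R11 (leakage)",
            "I(R12+R22)", "-xi_bar*R52",
        ]
        labels22 = [
            "psi12", "-R22", "-R32", "-R42-lam*Nt1", "-lam*I",
            "y-leakage block", "I(R11+R21)", "mu_bar*R51", "-mu_bar*R51",
        ]
        min_eigs_1 = np.full(7, np.inf)
        min_eigs_2 = np.full(9, np.inf)
        zero_1 = np.ones(7, bool)
        for v in self._probe_assignments(rng_seed):
            g11 = _lambda11_grid(v, self.model, self.fidelity)
            g22 = _lambda22_grid(v, self.model, self.sector, self.fidelity)
            for i in range(7):
                w = np.linalg.eigvalsh(_sym(g11[i][i]))
                min_eigs_1[i] = min(min_eigs_1[i], w[0])
                zero_1[i] &= bool(np.all(np.abs(g11[i][i]) < 1e-12))
            for i in range(9):
                w = np.linalg.eigvalsh(_sym(g22[i][i]))
                min_eigs_2[i] = min(min_eigs_2[i], w[0])
        for i in range(7):
            # an identically-zero block is diagnosed on the Lambda2 side
            if min_eigs_1[i] >= -1e-9 and not zero_1[i]:
                return f"Lambda1 diagonal block {i + 1} ({labels11[i]})"
        for i in range(9):
            if min_eigs_2[i] >= -1e-9:
                # zero diagonal blocks also rule out strict definiteness
                return f"Lambda2 diagonal block {i + 1} ({labels22[i]})"
        if self.mode == "nominal" and self.fidelity == "paper-faithful":
            return "trailing +I diagonal block"
        return None

    # -- solver interface ----------------------------------------------

    def initial_values(self) -> dict:
        n, l = self.n, self.model.l
        v = {name: np.eye(n) for name in _R_NAMES}
        # start with the first-window matrices large and the summed-window
        # matrices small, which is where feasible points tend to live
        v["R11"] = 10.0 * np.eye(n)
        v["R12"] = 10.0 * np.eye(n)
        for name in ("R31", "R32", "R41", "R42", "R51", "R52"):
            v[name] = 0.1 * np.eye(n)
        v.update(lam=1.0, eps1=1.0, eps2=1.0)
        if self.fidelity == "repaired":
            v.update(Q1=2.0 * np.eye(n), Q2=2.0 * np.eye(n), lam2=1.0)
        if self.gamma is None and self.mode in ("hinf", "synthesis"):
            v["gamma2"] = 1000.0
        if self.synthesis:
            v.update(
                X1=np.zeros((n, n)), X2=np.zeros((n, l)),
                Y1=np.zeros((n, n)), Y2=np.zeros((n, l)),
            )
        return v

    def bounds(self, scalar_min: float = 1e-7, box: float = 1e3):
        lo = np.full(self.layout.size, -box)
        hi = np.full(self.layout.size, box)
        i = 0
        for name, kind, shape in self.layout.entries:
            if kind == "scalar":
                lo[i] = scalar_min
                hi[i] = 1e6 if name == "gamma2" else box
                i += 1
            elif kind == "sym":
                i += shape[0] * (shape[0] + 1) // 2
            else:
                i += shape[0] * shape[1]
        return lo, hi


def _make_layout(
    model: GRNModel, mode: str, gamma: Optional[float], fidelity: str
) -> VariableLayout:
    n, l = model.n, model.l
    entries = [(name, "sym", (n, n)) for name in _R_NAMES]
    entries.append(("lam", "scalar", ()))
    if mode != "nominal":
        entries.append(("eps1", "scalar", ()))
        entries.append(("eps2", "scalar", ()))
    if fidelity == "repaired":
        entries += [("Q1", "sym", (n, n)), ("Q2", "sym", (n, n)),
                    ("lam2", "scalar", ())]
    if mode in ("hinf", "synthesis") and gamma is None:
        entries.append(("gamma2", "scalar", ()))
    if mode == "synthesis":
        entries += [
            ("X1", "full", (n, n)), ("X2", "full", (n, l)),
            ("Y1", "full", (n, n)), ("Y2", "full", (n, l)),
        ]
    return VariableLayout(entries)


# --------------------------------------------------------------------------
# public constructors
# --------------------------------------------------------------------------


def assemble_analysis(
    model: GRNModel,
    gains: EstimatorGains,
    sector: SectorBounds,
    fidelity: str = "repaired",
) -> LMIProblem:
    """Stability analysis LMIs for given gains (no disturbance row)."""
    return LMIProblem(
        mode="analysis", fidelity=fidelity, model=model, sector=sector,
        gains=gains, gamma=None, layout=_make_layout(model, "analysis", None, fidelity),
    )


def assemble_hinf(
    model: GRNModel,
    gains: EstimatorGains,
    sector: SectorBounds,
    gamma: Optional[float] = None,
    fidelity: str = "repaired",
) -> LMIProblem:
    """Disturbance-attenuation LMIs for given gains.

    ``gamma=None`` leaves gamma**2 as a decision scalar.
    """
    return LMIProblem(
        mode="hinf", fidelity=fidelity, model=model, sector=sector,
        gains=gains, gamma=gamma, layout=_make_layout(model, "hinf", gamma, fidelity),
    )


def assemble_synthesis(
    model: GRNModel,
    sector: SectorBounds,
    gamma: Optional[float] = None,
    fidelity: str = "repaired",
) -> LMIProblem:
    """Gain-synthesis LMIs: linear in X1, X2, Y1, Y2 and the R-matrices."""
    return LMIProblem(
        mode="synthesis", fidelity=fidelity, model=model, sector=sector,
        gains=None, gamma=gamma, layout=_make_layout(model, "synthesis", gamma, fidelity),
    )


def assemble_nominal(
    model: GRNModel,
    gains: EstimatorGains,
    sector: SectorBounds,
    fidelity: str = "repaired",
) -> LMIProblem:
    """Uncertainty-free reduced form; rejects models with uncertainty."""
    if model.uncertainty is not None and not model.uncertainty.is_zero():
        raise ValueError("nominal mode requires a model without uncertainty")
    return LMIProblem(
        mode="nominal", fidelity=fidelity, model=model, sector=sector,
        gains=gains, gamma=None, layout=_make_layout(model, "nominal", None, fidelity),
    )


# --------------------------------------------------------------------------
# solving
# --------------------------------------------------------------------------


@dataclass
class SynthesisResult:
    """Solver outcome: status, variable values, margins, recovered gains."""

    status: str                      # feasible | infeasible | numerical-failure
    problem: LMIProblem
    values: Optional[dict] = None
    theta: Optional[np.ndarray] = None
    margins: Optional[tuple[float, float]] = None   # min eig of -L1, -L2
    gains: Optional[EstimatorGains] = None
    diagnosis: Optional[str] = None
    cond_R21: Optional[float] = None
    cond_R22: Optional[float] = None
    worst_eig: Optional[float] = None


def solve(
    problem: LMIProblem,
    eps_strict: float = 1e-7,
    seed: int = 0,
    maxiter: int = 400,
    restarts: int = 2,
    skip_diagnosis: bool = False,
    x0_values: Optional[dict] = None,
) -> SynthesisResult:
    """Solve the LMI system; strict inequalities become ``<= -eps_strict I``.

    Infeasibility by sign-forced diagonal block is certified analytically
    before any numerical work.  On feasibility the result carries the
    decision-variable values, per-matrix margins (smallest eigenvalue of
    -Lambda at the solution), and -- for synthesis problems -- the recovered
    estimator gains.
    """
    if not skip_diagnosis:
        diag = problem.forced_positive_diagonal()
        if diag is not None:
            return SynthesisResult(
                status="infeasible", problem=problem, diagnosis=diag
            )

    layout = problem.layout
    nvar = layout.size

    def lmat1(theta):
        return problem.assemble_theta(theta)[0] + eps_strict * np.eye(problem.dims()[0])

    def lmat2(theta):
        return problem.assemble_theta(theta)[1] + eps_strict * np.eye(problem.dims()[1])

    blocks = [
        extract_affine(lmat1, nvar, "Lambda1"),
        extract_affine(lmat2, nvar, "Lambda2"),
    ]
    # positive-definiteness of the R-matrices: eps_pd I - R <= 0
    n = problem.n
    eps_pd = 1e-3
    i = 0
    for name, kind, shape in layout.entries:
        if kind == "sym":
            m = n * (n + 1) // 2
            idx = slice(i, i + m)

            def pd_block(theta, idx=idx):
                return eps_pd * np.eye(n) - _sym_from_vech(theta[idx], n)

            blocks.append(extract_affine(pd_block, nvar, f"PD:{name}"))
            i += m
        elif kind == "full":
            i += shape[0] * shape[1]
        else:
            i += 1

    lo, hi = problem.bounds(scalar_min=eps_strict)
    solver = SpectralSolver(blocks, lo, hi)
    x0 = layout.pack(x0_values if x0_values is not None else problem.initial_values())
    theta, worst = solver.solve(x0=x0, maxiter=maxiter, restarts=restarts, seed=seed)

    values = layout.unpack(theta)
    L1, L2 = problem.assemble(values)
    margins = (
        -float(np.linalg.eigvalsh(L1)[-1]),
        -float(np.linalg.eigvalsh(L2)[-1]),
    )
    feasible = worst <= 0.0
    res = SynthesisResult(
        status="feasible" if feasible else "infeasible",
        problem=problem,
        values=values,
        theta=theta,
        margins=margins,
        worst_eig=worst,
        cond_R21=float(np.linalg.cond(values["R21"])),
        cond_R22=float(np.linalg.cond(values["R22"])),
    )
    if not feasible:
        # distinguish numerical failure from a clean negative answer is not
        # possible for a local spectral method; report the achieved value
        res.status = "infeasible"
        res.diagnosis = f"best worst-eigenvalue {worst:.3e} > 0 (numerical search)"
        return res
    if problem.synthesis:
        res.gains = recover_gains(res)
    return res


def recover_gains(
    result: SynthesisResult, cond_threshold: float = 1e8
) -> EstimatorGains:
    """Back out estimator gains from the synthesis change of variables.

    Solves the linear systems ``R21 Ax = X1``, ``R21 Bx = X2``,
    ``R22 Ay = Y1``, ``R22 By = Y2`` (no explicit inversion) and checks both
    the conditioning of R21/R22 and the solve residuals.
    """
    v = result.values
    if v is None or "X1" not in v:
        raise ValueError("result does not carry synthesis variables")
    R21, R22 = v["R21"], v["R22"]
    for name, mat in (("R21", R21), ("R22", R22)):
        c = np.linalg.cond(mat)
        if c > cond_threshold:
            raise ValueError(
                f"{name} too ill-conditioned for gain recovery (cond={c:.2e})"
            )
    Ax = np.linalg.solve(R21, v["X1"])
    Bx = np.linalg.solve(R21, v["X2"])
    Ay = np.linalg.solve(R22, v["Y1"])
    By = np.linalg.solve(R22, v["Y2"])
    for lhs, rhs, sol, name in (
        (R21, v["X1"], Ax, "Ax"), (R21, v["X2"], Bx, "Bx"),
        (R22, v["Y1"], Ay, "Ay"), (R22, v["Y2"], By, "By"),
    ):
        resid = np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30)
        if rhs.any() and resid > 1e-9:
            raise ValueError(f"gain recovery residual too large for {name}: {resid:.2e}")
    return EstimatorGains(Ax=Ax, Ay=Ay, Bx=Bx, By=By)


def minimize_gamma(
    model: GRNModel,
    sector: SectorBounds,
    gains: Optional[EstimatorGains] = None,
    fidelity: str = "repaired",
    seed: int = 0,
    rel_tol: float = 0.02,
    max_bisect: int = 14,
) -> tuple[float, SynthesisResult]:
    """Smallest feasible attenuation level by bisection on gamma.

    With ``gains=None`` the synthesis LMIs are used (gamma**2 free in phase
    one, then fixed-gamma bisection warm-started from the last feasible
    point); otherwise the fixed-gain attenuation LMIs.
    """

    def build(gamma):
        if gains is None:
            return assemble_synthesis(model, sector, gamma=gamma, fidelity=fidelity)
        return assemble_hinf(model, gains, sector, gamma=gamma, fidelity=fidelity)

    free = build(None)
    res = solve(free, seed=seed)
    if res.status != "feasible":
        return float("inf"), res
    g_hi = float(np.sqrt(res.values["gamma2"]))
    best = res
    lo, hi = 1e-4, g_hi
    warm = dict(res.values)
    warm.pop("gamma2", None)
    while hi / max(lo, 1e-12) > 1 + rel_tol and max_bisect > 0:
        mid = float(np.sqrt(lo * hi))
        prob = build(mid)
        r = solve(prob, seed=seed, x0_values=warm, restarts=1)
        if r.status == "feasible":
            hi, best = mid, r
            warm = dict(r.values)
        else:
            lo = mid
        max_bisect -= 1
    return hi, best


# --------------------------------------------------------------------------
# matrix lemmas
# --------------------------------------------------------------------------


def schur_equivalence(
    Omega1: np.ndarray, Omega2: np.ndarray, Omega3: np.ndarray
) -> bool:
    """Schur-complement equivalence, evaluated from both sides.

    Checks ``Omega1 + Omega3' Omega2^(-1) Omega3 < 0`` and the negative
    definiteness of ``[[Omega1, Omega3'], [Omega3, -Omega2]]`` by
    independent dense eigendecompositions, asserts they agree, and returns
    the shared truth value.  Omega2 must be symmetric positive definite.
    """
    O1 = np.asarray(Omega1, dtype=float)
    O2 = np.asarray(Omega2, dtype=float)
    O3 = np.asarray(Omega3, dtype=float)
    if not np.allclose(O1, O1.T, atol=1e-10):
        raise ValueError("Omega1 must be symmetric")
    if not np.allclose(O2, O2.T, atol=1e-10):
        raise ValueError("Omega2 must be symmetric")
    if np.min(np.linalg.eigvalsh(O2)) <= 0:
        raise ValueError("Omega2 must be positive definite")
    reduced = O1 + O3.T @ np.linalg.solve(O2, O3)
    lhs = bool(np.max(np.linalg.eigvalsh(reduced)) < 0)
    big = np.block([[O1, O3.T], [O3, -O2]])
    rhs = bool(np.max(np.linalg.eigvalsh(big)) < 0)
    if lhs != rhs:
        raise AssertionError(
            "Schur complement equivalence violated (numerical degeneracy?)"
        )
    return lhs


def series_inequality_slack(M: np.ndarray, a: np.ndarray, xs: np.ndarray) -> float:
    """Slack of the weighted-series quadratic inequality.

    For PSD M, weights a_i >= 0 and vectors x_i,

        (sum a_i x_i)' M (sum a_i x_i) <= (sum a_i) * sum a_i x_i' M x_i.

    Returns rhs - lhs (non-negative when the inequality holds).
    """
    M = np.asarray(M, dtype=float)
    a = np.asarray(a, dtype=float)
    xs = np.asarray(xs, dtype=float)
    s = (a[:, None] * xs).sum(axis=0)
    lhs = float(s @ M @ s)
    rhs = float(a.sum() * np.sum(a * np.einsum("ij,jk,ik->i", xs, M, xs)))
    return rhs - lhs
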
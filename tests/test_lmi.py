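"""LMI assembly and solver tests: block dimensions, symmetry, affinity,
mode relationships, Schur-complement oracle, gain recovery."""

import numpy as np
import pytest

from grnest.fixtures import example_4_1, example_4_2, random_stable_model
from grnest.lmi import (
    SynthesisResult,
    assemble_analysis,
    assemble_hinf,
    assemble_nominal,
    assemble_synthesis,
    recover_gains,
    schur_equivalence,
    solve,
)
from grnest.model import EstimatorGains, SectorBounds
from grnest.sdp import AffineBlock, SpectralSolver, check_affine, extract_affine


@pytest.fixture(scope="module")
def fx41b():
    return example_4_1("4.1b")


def _rand_values(problem, rng):
    v = {}
    for name, kind, shape in problem.layout.entries:
        if kind == "sym":
            a = rng.standard_normal(shape)
            v[name] = a @ a.T + 0.2 * np.eye(shape[0])
        elif kind == "full":
            v[name] = rng.standard_normal(shape)
        else:
            v[name] = float(rng.uniform(0.2, 3.0))
    return v


class TestAssemblyShapes:
    @pytest.mark.parametrize(
        "builder,dims",
        [
            ("analysis", (38, 46)),
            ("hinf", (40, 48)),
            ("synthesis", (40, 48)),
            ("nominal", (38, 46)),
        ],
    )
    def test_block_dimensions_n2(self, fx41b, builder, dims):
        sector = fx41b.sector
        if builder == "analysis":
            p = assemble_analysis(fx41b.model, fx41b.gains, sector)
        elif builder == "hinf":
            p = assemble_hinf(fx41b.model, fx41b.gains, sector, gamma=1.0)
        elif builder == "synthesis":
            p = assemble_synthesis(fx41b.model, sector, gamma=1.0)
        else:
            p = assemble_nominal(
                fx41b.model.without_uncertainty(), fx41b.gains, sector
            )
        assert p.dims() == dims
        L1, L2 = p.assemble(p.initial_values())
        assert L1.shape == (dims[0], dims[0]) and L2.shape == (dims[1], dims[1])

    @pytest.mark.parametrize("fidelity", ["paper-faithful", "repaired"])
    def test_assembled_matrices_symmetric(self, fx41b, fidelity):
        p = assemble_hinf(
            fx41b.model, fx41b.gains, fx41b.sector, gamma=2.0, fidelity=fidelity
        )
        rng = np.random.default_rng(0)
        for _ in range(3):
            L1, L2 = p.assemble(_rand_values(p, rng))
            assert np.abs(L1 - L1.T).max() <= 1e-12
            assert np.abs(L2 - L2.T).max() <= 1e-12

    def test_assembly_is_affine_in_decisions(self, fx41b):
        p = assemble_synthesis(fx41b.model, fx41b.sector, gamma=1.5)
        nvar = p.layout.size
        rng = np.random.default_rng(1)
        for which in (0, 1):
            blk = extract_affine(
                lambda th, w=which: p.assemble_theta(th)[w], nvar
            )
            check_affine(
                lambda th, w=which: p.assemble_theta(th)[w], blk, rng, n_points=2
            )

    def test_full_observation_zeroes_variance_rows(self, fx41b):
        """alpha0 = beta0 = 1 means no dropout: sigma_alpha = 0, so the
        variance rows of the S blocks vanish."""
        import copy

        m = copy.copy(fx41b.model)
        m.alpha0 = 1.0
        m.beta0 = 1.0
        p = assemble_analysis(m, fx41b.gains, fx41b.sector)
        v = p.initial_values()
        L1, _ = p.assemble(v)
        n = 2
        # S1 variance row is block-row 3 of the J section (offset 7n + 2n)
        row = slice(7 * n + 2 * n, 7 * n + 3 * n)
        assert np.all(L1[row, : 7 * n] == 0)


class TestModeRelationships:
    def test_hinf_reduces_to_analysis_without_disturbance_row(self, fx41b):
        """Deleting the disturbance block row/column of the attenuation form
        recovers the pure stability form entrywise (printed fidelity)."""
        kw = dict(fidelity="paper-faithful")
        pa = assemble_analysis(fx41b.model, fx41b.gains, fx41b.sector, **kw)
        ph = assemble_hinf(fx41b.model, fx41b.gains, fx41b.sector, gamma=3.0, **kw)
        rng = np.random.default_rng(2)
        v = _rand_values(ph, rng)
        La1, La2 = pa.assemble(v)
        Lh1, Lh2 = ph.assemble(v)
        n = 2
        keep1 = np.r_[0 : 7 * n, 8 * n : 20 * n]
        keep2 = np.r_[0 : 9 * n, 10 * n : 24 * n]
        assert np.allclose(Lh1[np.ix_(keep1, keep1)], La1, atol=1e-12)
        assert np.allclose(Lh2[np.ix_(keep2, keep2)], La2, atol=1e-12)

    @pytest.mark.parametrize("fidelity", ["paper-faithful", "repaired"])
    def test_synthesis_substitution_identity(self, fx41b, fidelity):
        """Substituting X1 = R21 Ax etc. into the synthesis blocks must
        reproduce the fixed-gain attenuation blocks entrywise."""
        rng = np.random.default_rng(3)
        ps = assemble_synthesis(fx41b.model, fx41b.sector, gamma=2.0,
                                fidelity=fidelity)
        v = _rand_values(ps, rng)
        gains = EstimatorGains(
            Ax=np.linalg.solve(v["R21"], v["X1"]),
            Bx=np.linalg.solve(v["R21"], v["X2"]),
            Ay=np.linalg.solve(v["R22"], v["Y1"]),
            By=np.linalg.solve(v["R22"], v["Y2"]),
        )
        ph = assemble_hinf(fx41b.model, gains, fx41b.sector, gamma=2.0,
                           fidelity=fidelity)
        Ls1, Ls2 = ps.assemble(v)
        Lh1, Lh2 = ph.assemble(v)
        scale = max(np.abs(Ls1).max(), np.abs(Ls2).max(), 1.0)
        assert np.abs(Ls1 - Lh1).max() / scale <= 1e-9
        assert np.abs(Ls2 - Lh2).max() / scale <= 1e-9

    def test_nominal_matches_uncertainty_free_analysis_core(self, fx41b):
        """With the uncertainty factors removed, the reduced uncertainty-free form equals
        the analysis form on the shared (state + coupling) coordinates."""
        m0 = fx41b.model.without_uncertainty()
        kw = dict(fidelity="paper-faithful")
        pn = assemble_nominal(m0, fx41b.gains, fx41b.sector, **kw)
        pa = assemble_analysis(m0, fx41b.gains, fx41b.sector, **kw)
        rng = np.random.default_rng(4)
        v = _rand_values(pa, rng)
        Ln1, Ln2 = pn.assemble(v)
        La1, La2 = pa.assemble(v)
        n = 2
        core1, core2 = 12 * n, 14 * n
        assert np.allclose(Ln1[:core1, :core1], La1[:core1, :core1], atol=1e-12)
        assert np.allclose(Ln2[:core2, :core2], La2[:core2, :core2], atol=1e-12)

    def test_nominal_rejects_uncertain_model(self, fx41b):
        with pytest.raises(ValueError):
            assemble_nominal(fx41b.model, fx41b.gains, fx41b.sector)


class TestSolve:
    def test_scalar_sanity_problem(self):
        """Find r > 0 with -r < 0: one variable, trivially feasible."""
        blk = AffineBlock("neg-r", A0=np.zeros((1, 1)), A=-np.ones((1, 1, 1)))
        pd = AffineBlock("r-pos", A0=1e-3 * np.eye(1), A=-np.ones((1, 1, 1)))
        s = SpectralSolver([blk, pd], lower=np.array([1e-6]), upper=np.array([10.0]))
        theta, worst = s.solve(x0=np.array([1.0]))
        assert worst < 0

    def test_sign_forced_block_diagnosed_without_solver(self, fx41b):
        p = assemble_synthesis(fx41b.model, fx41b.sector, fidelity="paper-faithful")
        r = solve(p)
        assert r.status == "infeasible"
        assert r.diagnosis is not None and "diagonal block" in r.diagnosis
        assert r.values is None        # no numerical search happened

    def test_solve_monotone_in_strictness(self, toy_model, hill_sector):
        p = assemble_synthesis(toy_model, hill_sector, fidelity="repaired")
        margins = []
        prev = None
        for eps in (1e-5, 1e-6, 1e-7):
            r = solve(p, eps_strict=eps, seed=0, restarts=0,
                      x0_values=prev)
            assert r.status == "feasible"
            margins.append(min(r.margins))
            prev = r.values
        assert all(m > 0 for m in margins)

    def test_resubstituted_margins(self, toy_synthesis):
        gamma, res = toy_synthesis
        L1, L2 = res.problem.assemble(res.values)
        assert np.linalg.eigvalsh(L1)[-1] <= -0.5e-7
        assert np.linalg.eigvalsh(L2)[-1] <= -0.5e-7


class TestGainRecovery:
    @staticmethod
    def _result_with(problem, values):
        return SynthesisResult(status="feasible", problem=problem, values=values)

    def test_identity_weight(self, fx41b):
        p = assemble_synthesis(fx41b.model, fx41b.sector)
        v = p.initial_values()
        v.update(R21=np.eye(2), X1=np.array([[1.0, 2.0], [3.0, 4.0]]))
        g = recover_gains(self._result_with(p, v))
        assert np.allclose(g.Ax, v["X1"])

    def test_scaled_identity_weight(self, fx41b):
        p = assemble_synthesis(fx41b.model, fx41b.sector)
        v = p.initial_values()
        v.update(R21=2.0 * np.eye(2), X2=np.eye(2))
        g = recover_gains(self._result_with(p, v))
        assert np.allclose(g.Bx, 0.5 * np.eye(2))

    def test_against_dense_solve_oracle(self, fx41b):
        rng = np.random.default_rng(8)
        p = assemble_synthesis(fx41b.model, fx41b.sector)
        for _ in range(10):
            a = rng.standard_normal((2, 2))
            R21 = a @ a.T + 0.5 * np.eye(2)
            X1 = rng.standard_normal((2, 2))
            v = p.initial_values()
            v.update(R21=R21, X1=X1)
            g = recover_gains(self._result_with(p, v))
            oracle = np.linalg.inv(R21) @ X1
            assert np.abs(g.Ax - oracle).max() <= 1e-10 * max(np.abs(oracle).max(), 1)

    def test_ill_conditioned_weight_rejected(self, fx41b):
        p = assemble_synthesis(fx41b.model, fx41b.sector)
        v = p.initial_values()
        v.update(R21=np.diag([1.0, 1e-12]))
        with pytest.raises(ValueError):
            recover_gains(self._result_with(p, v))


class TestSchurEquivalence:
    def test_scalar_true_case(self):
        assert schur_equivalence([[-1.0]], [[1.0]], [[0.0]]) is True

    def test_scalar_false_case(self):
        # -1 + 2 * 1 * 2 = 3 > 0, and the 2x2 matrix has a positive eigenvalue
        assert schur_equivalence([[-1.0]], [[1.0]], [[2.0]]) is False

    def test_non_pd_inner_block_rejected(self):
        with pytest.raises(ValueError):
            schur_equivalence([[-1.0]], [[-1.0]], [[0.0]])

    def test_random_instances_agree(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            d1 = int(rng.integers(1, 7))
            d2 = int(rng.integers(1, 7))
            O1 = rng.standard_normal((d1, d1))
            O1 = (O1 + O1.T) / 2 - float(rng.uniform(0, 2)) * np.eye(d1)
            a = rng.standard_normal((d2, d2))
            O2 = a @ a.T + 0.1 * np.eye(d2)
            O3 = rng.standard_normal((d2, d1))
            schur_equivalence(O1, O2, O3)   # raises on disagreement
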
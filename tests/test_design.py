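"""Fisher-engine tests: Hessian correctness, D-optimal design, symmetry."""

import numpy as np
import pytest

from arraysense import (
    ArrayParams,
    MixtureComposition,
    chemical_potentials,
    generate_mixture_dataset,
    mixture_occupancies,
)
from arraysense.bayes import ArrayLikelihood, SamplerSettings
from arraysense.design import (
    DesignProblem,
    concentration_hessian,
    diagnose_array,
    discrimination_thresholds,
    enumerate_optima,
    optimize_design,
    robustness_scan,
)
from arraysense.simulate import default_series


def _fd_hessian(params, comp, mu0, replicates, const, eps=1e-6):
    """Finite-difference oracle: H from central differences of the responses."""
    series = default_series(const=const)
    ref = comp.reference_index
    free = [i for i in range(len(comp.ligand_ids)) if i != ref]

    def curves(theta):
        x = comp.x.copy()
        x[free] = theta[:-1]
        c = MixtureComposition(list(comp.ligand_ids), x / x[ref],
                               comp.ligand_ids[ref])
        out = []
        for j in range(params.n_receptors):
            I = []
            for mt in theta[-1] + series.offsets:
                mu = chemical_potentials(c, mt, const)
                p, _ = mixture_occupancies(params.dG[j], mu, const)
                I.append(params.eff[j] @ p)
            out.append(np.array(I))
        return out

    theta0 = np.concatenate([comp.x[free], [mu0]])
    J = [[] for _ in range(params.n_receptors)]
    for k in range(theta0.size):
        tp, tm = theta0.copy(), theta0.copy()
        tp[k] += eps
        tm[k] -= eps
        up, um = curves(tp), curves(tm)
        for j in range(params.n_receptors):
            J[j].append((up[j] - um[j]) / (2 * eps))
    H = sum(replicates / params.sigma[j] ** 2
            * (np.asarray(J[j]) @ np.asarray(J[j]).T)
            for j in range(params.n_receptors))
    return H


class TestConcentrationHessian:
    def test_matches_finite_difference_oracle(self, const):
        rng = np.random.default_rng(17)
        params = ArrayParams(["R1", "R2"], ["L1", "L2", "L3"],
                             rng.uniform(-10, -4, (2, 3)),
                             rng.uniform(0, 1, (2, 3)),
                             [0.03, 0.06], [0.02, 0.03])
        comp = MixtureComposition(["L1", "L2", "L3"], [1.0, 0.7, 2.3], "L1")
        mu0 = const.mu_of_concentration(4e-4)
        rep = concentration_hessian(params, comp, mu0, replicates=4)
        H_fd = _fd_hessian(params, comp, mu0, 4, const)
        rel = np.max(np.abs(H_fd - rep.H)) / np.max(np.abs(rep.H))
        assert rel < 1e-4

    def test_matches_loglikelihood_curvature_at_zero_residuals(self, const,
                                                               mu0_1mM):
        """H equals the FD Hessian of -logL at truth on noise-free data."""
        params = ArrayParams(["R1", "R2"], ["L1", "L2"],
                             [[-8.0, -6.5], [-5.5, -7.5]],
                             [[0.9, 0.1], [0.3, 0.8]], [0.0, 0.0], [0.02, 0.03])
        clean = ArrayParams(list(params.receptor_ids), list(params.ligand_ids),
                            params.dG, params.eff, params.bg, [1e-12, 1e-12])
        comp = MixtureComposition(["L1", "L2"], [1.0, 0.6], "L1")
        data = generate_mixture_dataset(clean, comp, mu0_1mM, seed=0)
        like = ArrayLikelihood(data, params, "L1", const=const, fit_sigma=False)
        theta0 = np.array([0.6, mu0_1mM])
        eps = 1e-5
        n = theta0.size
        H_fd = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                t = [theta0.copy() for _ in range(4)]
                t[0][a] += eps; t[0][b] += eps
                t[1][a] += eps; t[1][b] -= eps
                t[2][a] -= eps; t[2][b] += eps
                t[3][a] -= eps; t[3][b] -= eps
                H_fd[a, b] = -(like(t[0]) - like(t[1]) - like(t[2]) + like(t[3])) / (4 * eps**2)
        rep = concentration_hessian(params, comp, mu0_1mM, replicates=4)
        assert np.max(np.abs(H_fd - rep.H)) / np.max(np.abs(rep.H)) < 1e-4

    def test_sigma_scaling_law(self, demo_params, mu0_1mM):
        comp = MixtureComposition.equal_parts(list(demo_params.ligand_ids))
        rep1 = concentration_hessian(demo_params, comp, mu0_1mM)
        scaled = ArrayParams(list(demo_params.receptor_ids),
                             list(demo_params.ligand_ids), demo_params.dG,
                             demo_params.eff, demo_params.bg,
                             3.0 * demo_params.sigma)
        rep3 = concentration_hessian(scaled, comp, mu0_1mM)
        np.testing.assert_allclose(rep1.H, 9.0 * rep3.H, rtol=1e-12)
        np.testing.assert_allclose(rep3.delta, 3.0 * rep1.delta, rtol=1e-9)

    def test_unbound_ligand_has_infinite_uncertainty(self, mu0_1mM):
        """A ligand no receptor binds leaves a null row: delta_x = inf."""
        params = ArrayParams(["R1"], ["seen", "ghost"], [[-8.0, 50.0]],
                             [[0.9, 0.5]], [0.0], [0.02])
        comp = MixtureComposition(["seen", "ghost"], [1.0, 1.0], "seen")
        rep = concentration_hessian(params, comp, mu0_1mM)
        assert rep.delta_of("x_ghost") == np.inf
        assert not np.isfinite(rep.condition)

    def test_det_invariant_under_receptor_relabelling(self, demo_params, mu0_1mM):
        comp = MixtureComposition.equal_parts(list(demo_params.ligand_ids))
        rep = concentration_hessian(demo_params, comp, mu0_1mM)
        perm = [2, 0, 3, 1]
        shuffled = ArrayParams([demo_params.receptor_ids[j] for j in perm],
                               list(demo_params.ligand_ids),
                               demo_params.dG[perm], demo_params.eff[perm],
                               demo_params.bg[perm], demo_params.sigma[perm])
        rep_p = concentration_hessian(shuffled, comp, mu0_1mM)
        assert rep.det == pytest.approx(rep_p.det, rel=1e-9)


@pytest.fixture(scope="module")
def one_r_two_l():
    problem = DesignProblem(1, 2)
    settings = SamplerSettings(n_live=100, stop_tolerance=1e-2,
                               max_iterations=3000, seed=1)
    return problem, optimize_design(problem, settings)


class TestOptimizeDesign:
    def test_optimum_pairs_agonist_with_antagonist(self, one_r_two_l):
        _, result = one_r_two_l
        eff = np.sort(result.eff.ravel())
        assert eff[0] < 0.05 and eff[1] > 0.95
        assert result.det > 0

    def test_optimum_discriminates_both_parameters(self, one_r_two_l):
        problem, result = one_r_two_l
        thr_x, thr_mu = discrimination_thresholds(problem.const)
        assert result.delta[0] < thr_x
        assert result.delta[1] < thr_mu

    def test_agonist_agonist_design_cannot_decode_jointly(self, one_r_two_l):
        """With both efficacies pinned to 1 the response collapses to one
        degree of freedom: (x, mu0) are jointly unidentifiable for any dG."""
        _, free_result = one_r_two_l
        pinned = DesignProblem(1, 2, efficacies_free=False)
        lo, hi = pinned.dG_bounds
        grid = np.linspace(lo, hi, 7)
        best_det = max(pinned.report(np.array([[g1, g2]]), np.ones((1, 2))).det
                       for g1 in grid for g2 in grid)
        assert best_det < 1e-6 * free_result.det
        result = optimize_design(pinned, SamplerSettings(
            n_live=60, stop_tolerance=1e-2, max_iterations=1800, seed=2))
        thr_x, thr_mu = discrimination_thresholds(pinned.const)
        assert not (result.delta[0] < thr_x and result.delta[1] < thr_mu)


class TestEnumerateOptima:
    def test_one_receptor_two_ligands_has_two_mirror_optima(self):
        problem = DesignProblem(1, 2)
        settings = SamplerSettings(n_live=80, stop_tolerance=1e-2,
                                   max_iterations=2400, seed=3)
        optima = enumerate_optima(problem, settings, n_starts=8)
        globals_ = [o for o in optima if o.is_global]
        patterns = {o.pattern for o in globals_}
        assert patterns == {(("A", "a"),), (("a", "A"),)}
        dets = [o.det for o in globals_]
        assert max(dets) / min(dets) < 1.01

    def test_two_receptor_three_ligand_symmetry_structure(self):
        """Three global maxima, each with one ligand antagonist to both
        receptors, plus genuine local maxima with other patterns."""
        problem = DesignProblem(2, 3)
        settings = SamplerSettings(n_live=100, stop_tolerance=1e-2,
                                   max_iterations=3000, seed=4)
        optima = enumerate_optima(problem, settings, n_starts=12)
        globals_ = [o for o in optima if o.is_global]
        assert len(globals_) == 3
        for o in globals_:
            shared_antagonist = any(
                all(row[i] == "a" for row in o.pattern) for i in range(3))
            assert shared_antagonist, o.pattern
        assert len(optima) > 3  # local maxima with distinct patterns exist

    def test_large_problems_rejected(self):
        with pytest.raises(ValueError):
            enumerate_optima(DesignProblem(4, 4))


class TestDiagnoseArray:
    def test_parallel_ligand_profiles_decode_worse(self, mu0_1mM):
        """A ligand nearly collinear with another is harder to pin down."""
        base = dict(bg=[0.0, 0.0], sigma=[0.02, 0.02])
        orthogonal = ArrayParams(["R1", "R2"], ["L1", "L2"],
                                 [[-9.0, -4.0], [-4.0, -9.0]],
                                 [[0.9, 0.1], [0.1, 0.9]], **base)
        parallel = ArrayParams(["R1", "R2"], ["L1", "L2"],
                               [[-9.0, -8.9], [-8.8, -9.0]],
                               [[0.9, 0.88], [0.9, 0.92]], **base)
        comp = MixtureComposition(["L1", "L2"], [1.0, 1.0], "L1")
        d_orth = diagnose_array(orthogonal, comp, mu0_1mM).hessian
        d_par = diagnose_array(parallel, comp, mu0_1mM).hessian
        assert d_par.delta_of("x_L2") > d_orth.delta_of("x_L2")

    def test_reoptimization_never_decreases_det(self, mu0_1mM):
        params = ArrayParams(["R1", "R2"], ["L1", "L2"],
                             [[-7.0, -6.0], [-6.5, -7.5]],
                             [[0.8, 0.4], [0.3, 0.9]], [0.0, 0.0], [0.02, 0.02])
        comp = MixtureComposition(["L1", "L2"], [1.0, 1.0], "L1")
        diag = diagnose_array(params, comp, mu0_1mM, improve=True)
        base_det = diag.hessian.det
        for mode in ("eff_only", "dG_only", "both"):
            assert diag.improvements[mode].det >= base_det * (1 - 1e-9), mode
        assert diag.improvements["both"].det >= \
            diag.improvements["eff_only"].det * (1 - 1e-9)


class TestDetLandscapeGrid:
    def test_grid_peaks_near_the_optimum(self, one_r_two_l):
        from arraysense.design import det_landscape_grid

        problem, result = one_r_two_l
        table = det_landscape_grid(problem, result.eff, n=13)
        assert len(table) == 13 * 13
        peak = table.loc[table["det"].idxmax()]
        # grid peak sits within one grid step of the polished optimum
        step = (problem.dG_bounds[1] - problem.dG_bounds[0]) / 12
        assert abs(peak["dG1"] - result.dG[0, 0]) <= step + 1e-9
        assert abs(peak["dG2"] - result.dG[0, 1]) <= step + 1e-9

    def test_only_defined_for_1r2l(self):
        from arraysense.design import det_landscape_grid

        with pytest.raises(ValueError):
            det_landscape_grid(DesignProblem(2, 2), np.ones((2, 2)))


class TestRobustnessScan:
    def test_retention_and_smooth_drift(self):
        problem = DesignProblem(1, 2)
        settings = SamplerSettings(n_live=80, stop_tolerance=1e-2,
                                   max_iterations=2400, seed=6)
        design = optimize_design(problem, settings)
        grid = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        table = robustness_scan(design, grid, settings=SamplerSettings(
            n_live=60, stop_tolerance=1e-2, max_iterations=1800, seed=7))
        at_design = table.loc[np.isclose(table["x_varied"], 1.0), "retention"]
        assert at_design.iloc[0] == pytest.approx(1.0, abs=0.02)
        assert (table["det_fixed"] > 0).all()
        assert (table["retention"] > 0.005).all()
        # re-optimized binding energies drift continuously (no wild jumps)
        dGs = np.array([row for row in table["dG_opt"]])
        assert np.max(np.abs(np.diff(dGs, axis=0))) < 4.0
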
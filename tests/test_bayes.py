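"""Inference-engine tests: likelihood oracles, nested sampling, Metropolis."""

import numpy as np
import pytest
from scipy.stats import kstest

from arraysense import (
    generate_calibration_curve,
    generate_mixture_dataset,
    log_likelihood_array,
    log_likelihood_single,
    metropolis_refine,
    nested_sampling,
    ArrayParams,
    MixtureComposition,
)
from arraysense.bayes import Prior, PriorSpec, SamplerSettings


class TestSingleCurveLikelihood:
    def test_zero_residuals_reduce_to_normalization(self):
        theta = (-7.0, 0.8, 0.05, 0.02)
        curve = generate_calibration_curve(*theta[:3], sigma=0.0, seed=0)
        M = len(curve)
        assert M == 36
        ll = log_likelihood_single(curve, theta)
        assert ll == pytest.approx(-M * np.log(0.02 * np.sqrt(2 * np.pi)))

    def test_doubling_sigma_costs_M_log2(self):
        curve = generate_calibration_curve(-7.0, 0.8, 0.05, sigma=0.0, seed=0)
        M = len(curve)
        l1 = log_likelihood_single(curve, (-7.0, 0.8, 0.05, 0.02))
        l2 = log_likelihood_single(curve, (-7.0, 0.8, 0.05, 0.04))
        assert l1 - l2 == pytest.approx(M * np.log(2))

    def test_matches_per_point_summation_oracle(self, const):
        rng = np.random.default_rng(42)
        curve = generate_calibration_curve(-6.5, 0.7, 0.08, sigma=0.05, seed=1,
                                           replicates=2)
        theta = (-6.2, 0.75, 0.06, 0.04)
        series = curve.series["R1"]
        expected = 0.0
        for _, row in curve.df.iterrows():
            mu = series.potentials()[int(row["point_index"])]
            w = np.exp((mu - theta[0]) / const.kT)
            model = theta[2] + theta[1] * w / (1 + w)
            expected += (-(row["intensity"] - model) ** 2 / (2 * theta[3] ** 2)
                         - np.log(theta[3] * np.sqrt(2 * np.pi)))
        assert log_likelihood_single(curve, theta) == pytest.approx(expected)

    def test_empty_dataset_rejected(self):
        import pandas as pd
        from arraysense.model import DATA_COLUMNS, ResponseDataset
        from arraysense.bayes import SingleCurveLikelihood

        empty = ResponseDataset(pd.DataFrame(columns=DATA_COLUMNS), {})
        with pytest.raises(ValueError):
            SingleCurveLikelihood(empty)


class TestArrayLikelihood:
    def test_one_receptor_one_ligand_reduces_to_single(self, const):
        params = ArrayParams(["R1"], ["L1"], [[-7.0]], [[0.8]], [0.05], [0.02])
        comp = MixtureComposition(["L1"], [1.0], "L1")
        mu0 = const.mu_of_concentration(1e-3)
        data = generate_mixture_dataset(params, comp, mu0, seed=3)
        ll_arr = log_likelihood_array(data, params, ([], mu0, [0.02]))
        ll_single = log_likelihood_single(data, (-7.0, 0.8, 0.05, 0.02, mu0))
        assert ll_arr == pytest.approx(ll_single)

    def test_ligand_permutation_symmetry(self, demo_params, const, mu0_1mM):
        comp = MixtureComposition(list(demo_params.ligand_ids),
                                  [1.0, 0.5, 2.0, 0.1], "L1")
        data = generate_mixture_dataset(demo_params, comp, mu0_1mM, seed=4)
        theta = ([0.5, 2.0, 0.1], mu0_1mM, [0.02] * 4)
        ll = log_likelihood_array(data, demo_params, theta, reference_ligand="L1")
        # permute ligand labels (keep L1 as reference) together with columns
        perm = [0, 2, 3, 1]
        permuted = ArrayParams(
            list(demo_params.receptor_ids),
            [demo_params.ligand_ids[i] for i in perm],
            demo_params.dG[:, perm], demo_params.eff[:, perm],
            demo_params.bg, demo_params.sigma)
        ll_p = log_likelihood_array(data, permuted, ([2.0, 0.1, 0.5], mu0_1mM,
                                                     [0.02] * 4),
                                    reference_ligand="L1")
        assert ll == pytest.approx(ll_p, rel=1e-12)

    def test_matches_direct_summation_oracle(self, const):
        from arraysense import chemical_potentials, mixture_occupancies

        params = ArrayParams(["R1", "R2"], ["L1", "L2"],
                             [[-8.0, -6.0], [-5.5, -7.5]],
                             [[0.9, 0.2], [0.4, 0.85]], [0.03, 0.06], [0.02, 0.03])
        comp = MixtureComposition(["L1", "L2"], [1.0, 0.7], "L1")
        mu0 = const.mu_of_concentration(5e-4)
        data = generate_mixture_dataset(params, comp, mu0, seed=5, replicates=2)
        sig = [0.025, 0.035]
        expected = 0.0
        for _, row in data.df.iterrows():
            j = params.receptor_index(row["receptor"])
            series = data.series[row["receptor"]]
            mt = mu0 + series.offsets[int(row["point_index"])]
            mu = chemical_potentials(comp, mt, const)
            p, _ = mixture_occupancies(params.dG[j], mu, const)
            model = params.bg[j] + params.eff[j] @ p
            expected += (-(row["intensity"] - model) ** 2 / (2 * sig[j] ** 2)
                         - np.log(sig[j] * np.sqrt(2 * np.pi)))
        got = log_likelihood_array(data, params, ([0.7], mu0, sig))
        assert got == pytest.approx(expected)

    def test_receptor_missing_from_params_raises(self, demo_params, const, mu0_1mM):
        comp = MixtureComposition.equal_parts(list(demo_params.ligand_ids))
        data = generate_mixture_dataset(demo_params, comp, mu0_1mM, seed=6)
        small = demo_params.subset(["R1", "R2"])
        with pytest.raises(KeyError):
            log_likelihood_array(data, small, ([1, 1, 1], mu0_1mM, [0.02] * 4),
                                 receptor_subset=["R1", "R4"])


class TestNestedSampling:
    def test_flat_likelihood_evidence_is_one_for_both_prior_kinds(self):
        priors = PriorSpec([Prior("a", "uniform", -3.0, 5.0),
                            Prior("b", "jeffreys", 1e-3, 10.0)])
        s = nested_sampling(lambda t: 0.0, priors,
                            SamplerSettings(n_live=50, seed=1))
        assert s.log_evidence == pytest.approx(0.0, abs=max(3 * s.log_evidence_err, 1e-6))

    def test_gaussian_evidence_matches_closed_form(self):
        sigma_l, width = 0.05, 2.0
        priors = PriorSpec([Prior("a", "uniform", -1.0, 1.0)])
        s = nested_sampling(lambda t: -t[0] ** 2 / (2 * sigma_l ** 2), priors,
                            SamplerSettings(n_live=100, seed=2))
        exact = np.log(sigma_l * np.sqrt(2 * np.pi) / width)
        assert abs(s.log_evidence - exact) < 3 * s.log_evidence_err

    def test_posterior_recovers_gaussian_moments(self):
        mu_t, sd_t = 0.3, 0.07
        priors = PriorSpec([Prior("a", "uniform", -1.0, 1.0)])
        s = nested_sampling(lambda t: -(t[0] - mu_t) ** 2 / (2 * sd_t ** 2), priors,
                            SamplerSettings(n_live=100, seed=3))
        m, sd = s["a"]
        assert m == pytest.approx(mu_t, abs=0.01)
        assert sd == pytest.approx(sd_t, rel=0.15)

    def test_deterministic_given_seed(self):
        priors = PriorSpec([Prior("a", "uniform", -1.0, 1.0)])
        runs = [nested_sampling(lambda t: -t[0] ** 2 / 0.02, priors,
                                SamplerSettings(n_live=30, seed=9))
                for _ in range(2)]
        assert runs[0].log_evidence == runs[1].log_evidence
        np.testing.assert_array_equal(runs[0].samples, runs[1].samples)

    def test_synthetic_curve_posterior_covers_truth(self, fast_settings):
        from arraysense.calibrate import fit_single_ligand

        truth = (-7.5, 0.85, 0.06, 0.02)
        curve = generate_calibration_curve(*truth[:3], sigma=truth[3], seed=11)
        entry = fit_single_ligand(curve, settings=fast_settings.with_seed(12))
        m, sd = entry.posterior["dG"]
        assert abs(m - truth[0]) < 2 * sd

    def test_nan_likelihood_raises(self):
        priors = PriorSpec([Prior("a", "uniform", 0.0, 1.0)])
        with pytest.raises(ValueError):
            nested_sampling(lambda t: np.nan, priors,
                            SamplerSettings(n_live=10, seed=0))

    def test_jeffreys_draws_are_log_uniform(self):
        priors = PriorSpec([Prior("s", "jeffreys", 1e-3, 1e3)])
        rng = np.random.default_rng(7)
        draws = priors.sample(rng, 2000)[:, 0]
        z = (np.log(draws) - np.log(1e-3)) / (np.log(1e3) - np.log(1e-3))
        assert kstest(z, "uniform").pvalue > 0.01


class TestMetropolisRefine:
    def test_gaussian_target_variance_within_5pct(self):
        sd_t = 0.05

        def ll(t):
            return -t[0] ** 2 / (2 * sd_t ** 2)

        s = metropolis_refine(ll, np.array([0.0]), n_samples=30_000,
                              step_scales=np.array([0.1]), seed=21)
        assert s.stds[0] == pytest.approx(sd_t, rel=0.05)
        assert 0.05 < s.acceptance_rate < 0.95

    def test_chain_is_reproducible(self):
        def ll(t):
            return -t[0] ** 2

        a = metropolis_refine(ll, np.array([0.1]), n_samples=500, seed=5)
        b = metropolis_refine(ll, np.array([0.1]), n_samples=500, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            metropolis_refine(lambda t: -np.inf, np.array([0.0]), n_samples=10)


class TestPriorSpec:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Prior("a", "uniform", 1.0, 1.0)
        with pytest.raises(ValueError):
            Prior("s", "jeffreys", -1.0, 1.0)
        with pytest.raises(ValueError):
            Prior("a", "gamma", 0.0, 1.0)

    def test_transform_hits_bounds(self):
        spec = PriorSpec([Prior("a", "uniform", -2.0, 4.0),
                          Prior("s", "jeffreys", 1e-2, 1e2)])
        np.testing.assert_allclose(spec.transform(np.array([0.0, 0.5])), [-2.0, 1.0])
        np.testing.assert_allclose(spec.transform(np.array([1.0, 1.0])), [4.0, 1e2])
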
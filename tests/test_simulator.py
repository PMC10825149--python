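import numpy as np
import pytest

from lambdascape import core, simulator, synthetic
from lambdascape.simulator import SimulationConfig

from conftest import MU_SUPPLY_SCALED


class TestNoiseCalibration:
    def test_perfect_correlation_means_no_noise(self):
        assert simulator.calibrate_noise(np.ones(10), 1.0) == 0.0

    def test_closed_form(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 200_000)  # unit variance
        sigma = simulator.calibrate_noise(values, 0.96)
        assert sigma == pytest.approx(np.sqrt(1 / 0.96 - 1), rel=1e-2)
        assert sigma == pytest.approx(0.2041, abs=2e-3)

    def test_empirical_correlation_matches_target(self, truth):
        values = truth["C"].values
        sigma = simulator.calibrate_noise(values, 0.96)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(200):
            a = values + rng.normal(0, sigma, 512)
            b = values + rng.normal(0, sigma, 512)
            rs.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(rs) == pytest.approx(0.96, abs=0.02)

    def test_invalid_target_rejected(self):
        for bad in (0.0, -0.5, 1.2):
            with pytest.raises(core.ValidationError):
                simulator.calibrate_noise(np.ones(5), bad)


class TestPerturbation:
    def test_zero_sigma_identity(self, truth):
        assert simulator.perturb_landscape(truth["C"], 0.0, 1) == truth["C"]

    def test_reproducible_and_reference_fixed(self, truth):
        a = simulator.perturb_landscape(truth["C"], 0.3, 7)
        b = simulator.perturb_landscape(truth["C"], 0.3, 7)
        assert a == b
        assert a["000000000"] == 0.0

    def test_missing_values_stay_missing(self):
        values = np.full(512, np.nan)
        values[0] = 0.0
        values[3] = 1.0
        landscape = core.FitnessLandscape(core.ENVIRONMENTS["C"], values)
        noisy = simulator.perturb_landscape(landscape, 0.5, 2)
        assert np.isnan(noisy.values[1])
        assert np.isfinite(noisy.values[3])

    def test_unbiased(self):
        landscape = core.FitnessLandscape(
            core.ENVIRONMENTS["C"], np.full(512, 2.0)
        )
        landscape.values[0] = 0.0
        draws = np.array(
            [
                simulator.perturb_landscape(landscape, 0.5, seed).values[9]
                for seed in range(2000)
            ]
        )
        se = 0.5 / np.sqrt(len(draws))
        assert abs(draws.mean() - 2.0) < 3 * se


class TestPopulationSI:
    def test_monomorphic_ancestor_is_zero(self):
        abundances = np.zeros(512)
        abundances[0] = 1e6
        assert simulator.population_si(abundances, np.zeros(512)) == 0.0

    def test_experimental_mixture_design_reproduces_axis_coordinates(self):
        """90% competitor + 10% library (net SI 0) places B at +0.7, D at -0.9."""
        si_b = 0.9 * 0.778 + 0.1 * 0.0
        si_d = 0.9 * -0.99 + 0.1 * 0.0
        mix = np.array([90.0, 10.0])
        assert simulator.population_si(mix, np.array([0.778, 0.0])) == pytest.approx(
            si_b
        )
        assert round(si_b, 1) == core.ENVIRONMENTS["B"].axis_coordinate
        assert simulator.population_si(mix, np.array([-0.99, 0.0])) == pytest.approx(
            si_d
        )
        assert round(si_d, 1) == core.ENVIRONMENTS["D"].axis_coordinate

    def test_empty_population_rejected(self):
        with pytest.raises(core.ValidationError):
            simulator.population_si(np.zeros(512), np.zeros(512))


class TestEffectiveLandscape:
    @pytest.fixture()
    def stack(self):
        rng = np.random.default_rng(3)
        return rng.normal(0, 1, (5, 512))

    @pytest.mark.parametrize("model", ["discrete_shifting", "continuous_shifting"])
    @pytest.mark.parametrize(
        "env,coord", [("E", -1.0), ("D", -0.9), ("C", 0.0), ("B", 0.7), ("A", 1.0)]
    )
    def test_node_identity(self, stack, model, env, coord):
        vec, label = simulator.effective_landscape(coord, stack, model)
        node = simulator._AXIS_ORDER.index(env)
        np.testing.assert_array_equal(vec, stack[node])

    def test_midpoint_interpolation_weights(self, stack):
        vec, label = simulator.effective_landscape(0.35, stack, "continuous_shifting")
        c = stack[simulator._AXIS_ORDER.index("C")]
        b = stack[simulator._AXIS_ORDER.index("B")]
        np.testing.assert_allclose(vec, 0.5 * c + 0.5 * b)
        assert "@0.500" in label

    def test_discrete_nearest_node(self, stack):
        vec, label = simulator.effective_landscape(0.36, stack, "discrete_shifting")
        assert label == "B"  # distance 0.34 to B beats 0.36 to C

    def test_discrete_midpoint_tie_prefers_central_node(self, stack):
        vec, label = simulator.effective_landscape(0.35, stack, "discrete_shifting")
        assert label == "C"  # |0.0| < |0.7|

    def test_out_of_range_si_clamped(self, stack):
        vec, _ = simulator.effective_landscape(-1.7, stack, "continuous_shifting")
        np.testing.assert_array_equal(vec, stack[0])

    def test_static_ignores_population_state(self, stack):
        for x in (-1.0, 0.2, 0.9):
            vec, label = simulator.effective_landscape(x, stack, "static_B")
            assert label == "B"
            np.testing.assert_array_equal(
                vec, stack[simulator._AXIS_ORDER.index("B")]
            )


class TestReproduce:
    def test_population_size_conserved(self):
        rng = np.random.default_rng(0)
        abundances = rng.multinomial(10_000, np.full(512, 1 / 512))
        out = simulator.reproduce(abundances, rng.normal(0, 1, 512), 10_000, 0.5, rng)
        assert out.sum() == 10_000

    def test_neutral_drift_probabilities(self):
        rng = np.random.default_rng(1)
        abundances = np.array([300, 700])
        draws = np.array(
            [simulator.reproduce(abundances, np.zeros(2), 1000, 0.5, rng) for _ in range(3000)]
        )
        assert draws[:, 0].mean() == pytest.approx(300, rel=0.02)

    def test_weighted_example_two_genotypes(self):
        # n=(100,100), S=(0, ln4), c=0.5 -> weights (1, 2) -> p=(1/3, 2/3)
        rng = np.random.default_rng(2)
        draws = np.array(
            [
                simulator.reproduce(
                    np.array([100, 100]), np.array([0.0, np.log(4)]), 300, 0.5, rng
                )
                for _ in range(4000)
            ]
        )
        assert draws[:, 1].mean() / 300 == pytest.approx(2 / 3, abs=0.01)

    def test_extinct_genotype_stays_extinct(self):
        rng = np.random.default_rng(3)
        out = simulator.reproduce(np.array([0, 100]), np.array([5.0, 0.0]), 100, 0.5, rng)
        assert out[0] == 0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(core.ValidationError):
            simulator.reproduce(np.zeros(4), np.zeros(4), 10, 0.5, 0)


class TestMutate:
    def test_zero_rate_identity(self):
        abundances = np.arange(512, dtype=np.int64)
        assert np.array_equal(simulator.mutate(abundances, 0.0, 0), abundances)

    def test_conservation_and_expected_flux(self):
        abundances = np.zeros(512, dtype=np.int64)
        N = 5_000_000_000
        abundances[0] = N
        mu = 7.7e-8
        moved = []
        for seed in range(20):
            out = simulator.mutate(abundances, mu, seed)
            assert out.sum() == N
            moved.append(N - out[0])
        expected = 9 * N * mu  # ~3465 mutants per generation
        se = np.sqrt(expected / len(moved))
        assert np.mean(moved) == pytest.approx(expected, abs=4 * se)

    def test_mutants_land_on_single_site_neighbours(self):
        abundances = np.zeros(512, dtype=np.int64)
        abundances[0] = 10_000_000
        out = simulator.mutate(abundances, 1e-5, 5)
        mutated = np.nonzero(out)[0]
        assert all(
            g == 0 or bin(g).count("1") == 1 for g in mutated
        )

    def test_toy_scale_high_rate_conserves(self):
        abundances = np.zeros(512, dtype=np.int64)
        abundances[0] = 50
        for seed in range(10):
            out = simulator.mutate(abundances, 0.2, seed)
            assert out.sum() == 50
            assert (out >= 0).all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(core.ValidationError):
            simulator.mutate(np.array([5]), 1.5, 0)


class TestEntropyAndEndpoints:
    def test_monomorphic_entropy_zero(self):
        abundances = np.zeros(512)
        abundances[3] = 100
        assert simulator.shannon_entropy(abundances) == 0.0

    def test_uniform_entropy(self):
        assert simulator.shannon_entropy(np.full(512, 10)) == pytest.approx(
            np.log(512)
        )

    def test_merging_never_increases_entropy(self):
        rng = np.random.default_rng(8)
        abundances = rng.integers(0, 100, 512).astype(float)
        h_full = simulator.shannon_entropy(abundances)
        merged = abundances.copy()
        merged[0] += merged[1]
        merged[1] = 0
        assert simulator.shannon_entropy(merged) <= h_full + 1e-12

    def test_endpoint_labels(self):
        classes = ["generalist"] * 512
        classes[5] = "L_specialist"
        classes[9] = "O_specialist"
        abundances = np.zeros(512)
        abundances[5] = 50
        abundances[9] = 50
        assert simulator.endpoint_phenotypes(abundances, classes) == "O+L"
        abundances[0] = 3  # ~2.9% generalist
        assert simulator.endpoint_phenotypes(abundances, classes) == "O+L+G"

    def test_abundance_cutoff_is_inclusive_at_threshold(self):
        classes = ["generalist"] * 512
        classes[1] = "O_specialist"
        abundances = np.zeros(512)
        abundances[0] = 976
        abundances[1] = 24  # 2.4% < 2.5% cutoff
        assert simulator.endpoint_phenotypes(abundances, classes) == "G"
        abundances[1] = 25
        abundances[0] = 975
        assert simulator.endpoint_phenotypes(abundances, classes) == "O+G"


class TestRunSimulation:
    def test_no_mutation_stays_monomorphic(self, truth):
        config = SimulationConfig(
            N=10_000, generations=50, mu=0.0, model="continuous_shifting", seed=0
        )
        trajectory = simulator.run_simulation(config, truth)
        assert np.allclose(trajectory.entropy, 0.0)
        assert trajectory.final_abundances[0] == 10_000
        assert trajectory.endpoint_label == "G"

    def test_deterministic_given_seed(self, truth):
        config = SimulationConfig(
            N=100_000, generations=40, mu=MU_SUPPLY_SCALED, seed=11
        )
        a = simulator.run_simulation(config, truth)
        b = simulator.run_simulation(config, truth)
        assert np.array_equal(a.final_abundances, b.final_abundances)
        assert np.array_equal(a.entropy, b.entropy)
        assert a.endpoint_label == b.endpoint_label

    def test_population_size_conserved_every_generation(self, truth):
        config = SimulationConfig(N=50_000, generations=30, mu=1e-4, seed=3)
        trajectory = simulator.run_simulation(config, truth)
        assert trajectory.final_abundances.sum() == 50_000

    def test_selection_dominance_on_static_landscape(self):
        """A strictly fittest one-step neighbour sweeps to near-fixation."""
        values = np.full(512, -1.0)
        values[0] = 0.0
        values[1] = 1.0  # single mutant at site 1 strictly fittest
        landscapes = {
            env_id: core.FitnessLandscape(env, values.copy())
            for env_id, env in core.ENVIRONMENTS.items()
        }
        wins = 0
        for seed in range(10):
            config = SimulationConfig(
                N=1_000_000,
                generations=300,
                mu=MU_SUPPLY_SCALED,
                model="static_C",
                target_r=1.0,
                seed=seed,
            )
            trajectory = simulator.run_simulation(config, landscapes)
            if trajectory.final_abundances[1] / 1_000_000 > 0.95:
                wins += 1
        assert wins >= 9

    def test_shifting_models_agree_when_population_pinned_to_node(self, truth):
        """With flat receptor landscapes every genotype has SI 0, the
        population sits exactly on node C, and the discrete and continuous
        rules produce identical dynamics."""
        flat = {}
        for env_id, env in core.ENVIRONMENTS.items():
            values = truth[env_id].values if env_id not in ("A", "E") else np.zeros(512)
            flat[env_id] = core.FitnessLandscape(env, values.copy())
        kwargs = dict(N=100_000, generations=40, mu=1e-4, target_r=1.0, seed=21)
        a = simulator.run_simulation(
            SimulationConfig(model="discrete_shifting", **kwargs), flat
        )
        b = simulator.run_simulation(
            SimulationConfig(model="continuous_shifting", **kwargs), flat
        )
        assert np.array_equal(a.final_abundances, b.final_abundances)
        np.testing.assert_array_equal(a.population_si, b.population_si)

    def test_invalid_config_rejected(self):
        with pytest.raises(core.ValidationError):
            SimulationConfig(N=0)
        with pytest.raises(core.ValidationError):
            SimulationConfig(mu=2.0)
        with pytest.raises(core.ValidationError):
            SimulationConfig(model="oscillating")


def test_replay_generation_count():
    assert simulator.replay_generation_count() == 280
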
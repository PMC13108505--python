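"""Parameter vector, priors, posterior terms and the MAP machinery."""

import numpy as np
import pytest

from vepfield.epileptor import SimulationConfig
from vepfield.inference import (
    InferenceProblem,
    OptimizerConfig,
    ParameterVector,
    _Objective,
    count_full_dimensionality,
    default_priors,
    log_likelihood,
    log_posterior,
    log_prior,
    map_estimate,
    pack,
    unpack,
)
from vepfield.synthetic import build_scenario, generate_brain, generate_connectome, generate_sensors


@pytest.fixture(scope="module")
def tiny_problem():
    """A deliberately small forward model for fast objective evaluations."""
    brain = generate_brain(n_regions_per_hemi=12, mesh_level=2, seed=1)
    K = generate_connectome(brain, seed=2)
    sensors = generate_sensors(brain, 2, 3, near_regions=[0, 3], seed=3)
    cfg = SimulationConfig(dt=0.05, n_steps=40, subsample_s=0.1)
    scenario = build_scenario(
        brain, K, sensors, ez_regions=[0], grid_degree=4, sim_config=cfg,
        n_augment=3, seed=4,
    )
    problem = InferenceProblem(
        space=scenario.space,
        local_op=scenario.local_op,
        connectome=K,
        bipolar_gain=scenario.gain.bipolar,
        sim_config=cfg,
        L_max=3,
    )
    return scenario, problem


class TestPackUnpack:
    def test_constant_map_is_monopole(self, tiny_problem):
        scenario, problem = tiny_problem
        n = scenario.space.n_sources
        maps = {m: np.full(n, v) for m, v in [("x_init", -2.0), ("z_init", 5.0), ("x0", -3.0)]}
        theta = pack(maps, scenario.space, L_max=3)
        for name in ("x_init", "z_init", "x0"):
            c = theta.coeffs[name]
            assert np.max(np.abs(c[:, 1:])) < 1e-10
            assert np.max(np.abs(c[:, 0])) > 0

    def test_projection_identity_on_bandlimited(self, tiny_problem, rng):
        scenario, problem = tiny_problem
        space = scenario.space
        from vepfield.harmonics import SphericalHarmonicTransform

        sht = SphericalHarmonicTransform(space.grid, 3)
        m = np.empty(space.n_sources)
        for h in range(2):
            m[space.hemisphere_slice(h)] = sht.inverse(rng.normal(size=16))
        m[space.n_cortical :] = rng.normal(size=space.brain.n_subcortical)
        maps = {"x_init": m, "z_init": m, "x0": m}
        rec = unpack(pack(maps, space, 3), space)
        for name in maps:
            assert np.max(np.abs(rec[name] - m)) < 1e-8

    def test_coefficient_count_at_lmax16(self):
        vec = ParameterVector(
            L_max=16,
            coeffs={m: np.zeros((2, 289)) for m in ("x_init", "z_init", "x0")},
            subcortical={m: np.zeros(18) for m in ("x_init", "z_init", "x0")},
            scalars={s: 0.0 for s in ("G", "tau", "eps", "alpha", "beta")},
        )
        assert vec.n_coeffs_per_map == 289
        assert vec.size() == 3 * 2 * 289 + 3 * 18 + 5

    def test_flatten_roundtrip(self, tiny_problem, rng):
        _, problem = tiny_problem
        n_sub = problem.space.brain.n_subcortical
        vec = rng.normal(size=3 * 2 * 16 + 3 * n_sub + 5)
        theta = ParameterVector.unflatten(vec, 3, n_sub)
        assert np.allclose(theta.flatten(), vec)


class TestDimensionality:
    def test_paper_scale_count(self):
        assert count_full_dimensionality(2 * 32768 + 18) == 196667

    def test_small_counts(self):
        assert count_full_dimensionality(1) == 8
        assert count_full_dimensionality(10) == 35

    def test_brain_argument(self, small_brain):
        n = sum(h.n_vertices for h in small_brain.hemispheres) + 18
        assert count_full_dimensionality(small_brain) == 3 * n + 5


class TestPriors:
    def test_table_defaults(self):
        priors = default_priors()
        assert priors["x0"].mean == -3.0 and priors["x0"].var == 0.5
        assert (priors["x0"].lb, priors["x0"].ub) == (-5.0, 0.0)
        assert priors["tau"].family == "uniform"
        assert (priors["tau"].lb, priors["tau"].ub) == (20.0, 100.0)
        assert priors["G"].var == 5.0
        for name in ("x_init", "z_init", "G", "eps", "alpha", "beta"):
            p = priors[name]
            assert p.lb < p.ub

    def test_maximum_at_prior_means(self, tiny_problem):
        scenario, problem = tiny_problem
        space = scenario.space
        n = space.n_sources
        maps = {
            "x_init": np.full(n, -3.0),
            "z_init": np.full(n, 5.0),
            "x0": np.full(n, -3.0),
        }
        theta = pack(maps, space, 3, scalars={"G": 1.0, "tau": 60.0, "eps": 0.1, "alpha": 0.0, "beta": 0.0})
        base = log_prior(theta, problem)
        moved = pack(
            {**maps, "x0": np.full(n, -2.0)}, space, 3,
            scalars={"G": 1.0, "tau": 60.0, "eps": 0.1, "alpha": 0.0, "beta": 0.0},
        )
        assert log_prior(moved, problem) < base

    def test_tau_outside_bounds_rejected(self, tiny_problem):
        scenario, problem = tiny_problem
        n = scenario.space.n_sources
        maps = {"x_init": np.full(n, -3.0), "z_init": np.full(n, 5.0), "x0": np.full(n, -3.0)}
        theta = pack(maps, scenario.space, 3, scalars={"tau": 150.0})
        assert log_prior(theta, problem) == -np.inf

    def test_matches_termwise_sum(self, tiny_problem, rng):
        scenario, problem = tiny_problem
        space = scenario.space
        maps = {
            "x_init": rng.uniform(-4.0, -2.0, space.n_sources),
            "z_init": rng.uniform(4.2, 5.8, space.n_sources),
            "x0": rng.uniform(-4.0, -1.0, space.n_sources),
        }
        # band-limit the maps so pack/unpack is lossless for the comparison
        maps = {k: unpack(pack(maps, space, 3), space)[k] for k in maps}
        maps = {k: np.clip(v, problem.priors[k].lb + 0.01, problem.priors[k].ub - 0.01) for k, v in maps.items()}
        scalars = {"G": 2.0, "tau": 50.0, "eps": 0.2, "alpha": 1.5, "beta": 0.3}
        theta = pack(maps, space, 3, scalars=scalars)
        rec = unpack(theta, space)
        expected = 0.0
        for name, vals in rec.items():
            p = problem.priors[name]
            expected += np.sum(-((vals - p.mean) ** 2) / (2 * p.var))
        for name in ("G", "eps", "alpha", "beta"):
            p = problem.priors[name]
            expected += -((scalars[name] - p.mean) ** 2) / (2 * p.var)
        assert log_prior(theta, problem) == pytest.approx(expected)


class TestLikelihood:
    def _gt_theta(self, scenario, problem):
        maps = {
            "x_init": np.full(scenario.space.n_sources, -2.0),
            "z_init": np.full(scenario.space.n_sources, 5.0),
            "x0": scenario.x0_true.astype(float),
        }
        return pack(
            maps, scenario.space, L_max=4,
            scalars={"G": scenario.params.G, "tau": scenario.params.tau,
                     "eps": 0.1, "alpha": 1.0, "beta": 0.0},
        )

    def test_noiseless_observation_attains_maximum(self, tiny_problem):
        scenario, problem = tiny_problem
        problem4 = InferenceProblem(
            space=problem.space, local_op=problem.local_op, connectome=problem.connectome,
            bipolar_gain=problem.bipolar_gain, sim_config=problem.sim_config, L_max=4,
        )
        theta = self._gt_theta(scenario, problem4)
        from vepfield.inference import _predict

        obs = _predict(theta, problem4).T[None]  # model's own output, zero residual
        ll = log_likelihood(theta, obs, problem4)
        expected_max = -obs.size * (np.log(0.1) + 0.5 * np.log(2 * np.pi))
        assert ll == pytest.approx(expected_max, rel=1e-9)

    def test_residual_increment_closed_form(self, tiny_problem):
        scenario, problem = tiny_problem
        problem4 = InferenceProblem(
            space=problem.space, local_op=problem.local_op, connectome=problem.connectome,
            bipolar_gain=problem.bipolar_gain, sim_config=problem.sim_config, L_max=4,
        )
        theta = self._gt_theta(scenario, problem4)
        from vepfield.inference import _predict

        base = _predict(theta, problem4).T
        obs = base.copy()
        obs[0, 3] += 0.5
        ll0 = log_likelihood(theta, base[None], problem4)
        ll1 = log_likelihood(theta, obs[None], problem4)
        assert ll0 - ll1 == pytest.approx(0.5**2 / (2 * 0.1**2))

    def test_matches_bruteforce_elementwise(self, tiny_problem, rng):
        scenario, problem = tiny_problem
        theta = self._gt_theta(scenario, problem)
        problem4 = InferenceProblem(
            space=problem.space, local_op=problem.local_op, connectome=problem.connectome,
            bipolar_gain=problem.bipolar_gain, sim_config=problem.sim_config, L_max=4,
        )
        obs = scenario.features.values[None] + rng.normal(0, 0.1, size=(3,) + scenario.features.values.shape)
        from vepfield.inference import _predict

        pred = _predict(theta, problem4)
        eps = 0.1
        brute = sum(
            -((obs[k].T - pred) ** 2).sum() / (2 * eps**2)
            - obs[k].size * (np.log(eps) + 0.5 * np.log(2 * np.pi))
            for k in range(3)
        )
        assert log_likelihood(theta, obs, problem4) == pytest.approx(brute, rel=1e-12)

    def test_posterior_decomposes(self, tiny_problem):
        scenario, problem = tiny_problem
        problem4 = InferenceProblem(
            space=problem.space, local_op=problem.local_op, connectome=problem.connectome,
            bipolar_gain=problem.bipolar_gain, sim_config=problem.sim_config, L_max=4,
        )
        theta = self._gt_theta(scenario, problem4)
        obs = scenario.features.values[None]
        lp = log_prior(theta, problem4)
        ll = log_likelihood(theta, obs, problem4)
        post = log_posterior(theta, obs, problem4)
        assert abs(post - (lp + ll)) < 1e-9 * abs(post)


class TestObjectiveGradient:
    def test_adjoint_matches_finite_differences(self, tiny_problem, rng):
        scenario, problem = tiny_problem
        from dataclasses import replace

        # double precision throughout: finite differences probe rounding
        # noise otherwise
        problem = replace(problem, coupling_single_precision=False)
        obj = _Objective(scenario.augmented, problem)
        u = obj.init_u(rng, 0.1)
        val, grad = obj.value_and_grad(u)
        assert np.isfinite(val) and np.isfinite(grad).all()
        h = 1e-6
        for i in rng.choice(len(u), size=12, replace=False):
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fd = (obj.value_and_grad(up)[0] - obj.value_and_grad(um)[0]) / (2 * h)
            assert abs(fd - grad[i]) < 1e-4 * max(1.0, abs(fd))

    def test_bound_transform_respects_boxes(self, tiny_problem, rng):
        scenario, problem = tiny_problem
        obj = _Objective(scenario.augmented, problem)
        u = obj.init_u(rng, 2.0)  # aggressive jitter
        theta = obj.theta_from_u(u)
        nat_maps, _ = obj.natural_maps(theta)
        for name, vals in nat_maps.items():
            p = problem.priors[name]
            assert (vals > p.lb).all() and (vals < p.ub).all()


class TestMapEstimate:
    def test_deterministic_given_seed(self, tiny_problem):
        scenario, problem = tiny_problem
        cfg = OptimizerConfig(n_steps=20, n_restarts=1, seed=9)
        r1 = map_estimate(scenario.augmented, problem, cfg)
        r2 = map_estimate(scenario.augmented, problem, cfg)
        assert np.array_equal(r1.u, r2.u)
        assert r1.objective == r2.objective

    def test_restarts_tracked(self, tiny_problem):
        scenario, problem = tiny_problem
        cfg = OptimizerConfig(n_steps=5, n_restarts=2, seed=0)
        res = map_estimate(scenario.augmented, problem, cfg)
        assert len(res.restart_objectives) == 2
        assert res.objective == min(res.restart_objectives)
        assert res.seeds == [0, 1]

    def test_objective_decreases(self, tiny_problem):
        scenario, problem = tiny_problem
        cfg = OptimizerConfig(n_steps=150, n_restarts=1, seed=3)
        res = map_estimate(scenario.augmented, problem, cfg)
        trace = res.traces[0]
        assert trace[-1] < trace[0]
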
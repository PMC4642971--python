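"""Error function, evolutionary strategy and observation-scaling fits."""

import numpy as np
import pandas as pd
import pytest

from il4redox.datasets import ExperimentDataset
from il4redox.fitting import (EsConfig, SimulationFailure, evolution_strategy,
                              fit_scaling, objective)
from il4redox.systems_model import ObservationScaling


def _dataset(rows):
    return ExperimentDataset(pd.DataFrame(
        rows, columns=["condition", "species", "time_min", "mean", "sem"]))


class TestObjectiveFormula:
    """The error weights residuals by measured value times its SEM."""

    @staticmethod
    def _err(y, e, sem):
        return float(np.sum(((np.asarray(y) - np.asarray(e))
                             / (np.asarray(e) * np.asarray(sem))) ** 2))

    def test_single_point_hand_example(self):
        # ((3 - 2) / (2 * 0.5))^2 = 1
        assert self._err([3.0], [2.0], [0.5]) == pytest.approx(1.0)

    def test_perfect_fit_is_zero(self):
        e = np.array([1.0, 2.0, 3.0])
        assert self._err(e, e, np.full(3, 0.1)) == 0.0

    def test_doubling_sem_quarters_error(self):
        y = np.array([1.2, 2.5, 0.7])
        e = np.array([1.0, 2.0, 1.0])
        s = np.array([0.2, 0.3, 0.1])
        assert self._err(y, e, 2 * s) == pytest.approx(self._err(y, e, s) / 4)

    def test_model_objective_matches_formula(self):
        # with identity scaling and a dataset pinned to simulated values,
        # the full pipeline objective equals the hand formula on residuals
        from il4redox.systems_model import Il4SystemsModel, STANDARD_CONDITIONS
        model = Il4SystemsModel()
        df = model.simulate_condition(STANDARD_CONDITIONS["IL4"])
        t = np.array([5.0, 30.0, 60.0])
        sim = np.interp(t, df["time_min"], df["pSTAT6"])
        e = sim * 1.1 + 0.05
        sem = np.full(3, 0.2)
        ds = _dataset([("IL4", "pSTAT6", tt, ee, ss)
                       for tt, ee, ss in zip(t, e, sem)])
        scale = ObservationScaling(alpha={"pSTAT6": 0.0}, beta={"pSTAT6": 1.0})
        got = objective({}, ds, model, scaling=scale,
                        plan={"pSTAT6": ("IL4",)})
        assert got == pytest.approx(self._err(sim, e, sem), rel=1e-6)

    def test_invalid_dataset_rejected(self):
        ds = _dataset([("IL4", "pSTAT6", 0.0, 1.0, 0.0)])
        from il4redox.systems_model import Il4SystemsModel
        with pytest.raises(ValueError):
            objective({}, ds, Il4SystemsModel(), plan={"pSTAT6": ("IL4",)})


class TestEvolutionStrategy:
    def test_sphere_minimum_found(self):
        target = np.array([0.3, -0.2, 0.1, 0.0, -0.4])

        def sphere(x):
            return float(np.sum((x - target) ** 2))

        cfg = EsConfig(population=30, parents=6, step=0.2,
                       max_generations=200, seed=4)
        x, f, trace, n_evals, n_fail = evolution_strategy(
            sphere, np.zeros(5), cfg)
        assert f < 1e-2
        assert np.allclose(x, target, atol=0.15)
        assert n_fail == 0

    def test_best_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6))

        def quad(x):
            return float(x @ (A.T @ A) @ x + np.sum(x))

        cfg = EsConfig(population=16, parents=4, max_generations=60, seed=2)
        _, _, trace, _, _ = evolution_strategy(quad, np.ones(6), cfg)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_fixed_seed_fixes_trajectory(self):
        def noisyish(x):
            return float(np.sum(x ** 2) + np.sin(10 * x[0]))

        cfg = EsConfig(population=10, parents=3, max_generations=30, seed=11)
        r1 = evolution_strategy(noisyish, np.full(3, 0.7), cfg)
        r2 = evolution_strategy(noisyish, np.full(3, 0.7), cfg)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[2] == r2[2]

    def test_failures_penalized_not_fatal(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if np.any(x > 0.8):
                raise SimulationFailure("blown up")
            return float(np.sum(x ** 2))

        cfg = EsConfig(population=12, parents=3, step=0.3,
                       max_generations=40, seed=5)
        x, f, _, _, n_fail = evolution_strategy(flaky, np.full(4, 0.5), cfg)
        assert f < 0.05
        assert n_fail > 0

    def test_hyper_mutation_escapes_stagnation(self):
        # a flat plateau objective stagnates; hyper-mutation must fire and
        # eventually reach the narrow basin far from the start
        def plateau(x):
            d = np.linalg.norm(x - 3.0)
            return float(min(1.0, d ** 2 / 25.0))

        cfg = EsConfig(population=20, parents=4, step=0.05, hyper_trigger=5,
                       hyper_factor=20.0, hyper_length=3,
                       max_generations=150, seed=8, bound_decades=5.0)
        x, f, trace, _, _ = evolution_strategy(plateau, np.zeros(4), cfg)
        assert f < 0.5  # moved off the unit plateau toward the basin


class TestFitScaling:
    def test_exact_affine_recovered(self):
        x = np.linspace(0, 2, 12)
        alpha, beta, flagged = fit_scaling(x, 2 * x + 1)
        assert alpha == pytest.approx(1.0, abs=1e-9)
        assert beta == pytest.approx(2.0, rel=1e-9)
        assert not flagged

    def test_constant_trajectory_flagged(self):
        with pytest.warns(UserWarning, match="unidentifiable"):
            _, beta, flagged = fit_scaling(np.ones(5),
                                           np.array([1., 2., 3., 2., 1.]))
        assert flagged
        assert beta == 1.0

    def test_constant_data_and_trajectory_not_flagged(self):
        alpha, beta, flagged = fit_scaling(np.full(5, 2.0), np.full(5, 7.0))
        assert not flagged
        assert alpha + 2.0 * beta == pytest.approx(7.0)

    def test_weighted_fit_prioritizes_precise_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        e = 2 * x + 1
        e[3] += 5.0  # outlier with huge uncertainty
        sems = np.array([0.01, 0.01, 0.01, 100.0])
        alpha, beta, _ = fit_scaling(x, e, sems)
        assert beta == pytest.approx(2.0, rel=0.05)
        assert alpha == pytest.approx(1.0, abs=0.1)
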
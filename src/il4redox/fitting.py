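"""Parameter estimation for the detailed IL-4 model.

The error function compares affinely scaled simulated observables
``y_ij(t)`` with measured means ``e_ij(t)`` weighted by both the
measured magnitude and its standard error:

    e = sum_i sum_j sum_t ((y_ij(t) - e_ij(t)) / (e_ij(t) * sigma_ij(t)))^2

over conditions i, species j and sampled times t.  Minimization uses a
(mu + lambda) evolutionary strategy in log10 parameter space with
Gaussian mutation and a hyper-mutation phase: when the best objective
stagnates for a trigger number of generations, the mutation step is
transiently magnified to kick the population out of local basins.
Per-species observation scalings (alpha, beta) are profiled out by
weighted linear least squares at every objective evaluation, keeping
them condition-independent by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import ExperimentDataset
from .systems_model import (STANDARD_CONDITIONS, OBSERVABLE_SPECIES,
                            Il4SystemsModel, ObservationScaling)

__all__ = ["EsConfig", "FitResult", "objective", "es_fit", "fit_scaling",
           "evolution_strategy", "TRAINING_PLAN", "DEFAULT_FREE_PARAMETERS"]

# Which (species, conditions) series train the model; redox perturbations
# (DPI, exogenous H2O2) are deliberately held out for validation.
TRAINING_PLAN = {
    "pSTAT6": ("IL4", "IL4+MG132", "IL4+CHX"),
    "STAT6": ("IL4", "IL4+MG132"),
    "SOCS3": ("IL4", "IL4+CHX"),
}

DEFAULT_FREE_PARAMETERS = [
    "k_act", "k_basal", "kon_phos", "kcat_phos", "kon_p1", "kcat_p1",
    "kon_p2", "kcat_p2", "k_socs_on", "k_socs_off", "k_socs_dp",
    "v_socs", "km_socs", "k_socs_deg", "k_stat_syn", "k_stat_deg",
    "k_stat_deg_u", "k_in", "k_out", "k_dpn",
    "k_ox1", "k_red1", "k_ox2", "k_red2",
]


class SimulationFailure(RuntimeError):
    pass


def _plan_from_dataset(dataset: ExperimentDataset, plan=None):
    pairs = []
    table = dataset.table
    for species, conditions in (plan or TRAINING_PLAN).items():
        for cond in conditions:
            sub = table[(table["species"] == species)
                        & (table["condition"] == cond)]
            if len(sub):
                pairs.append((cond, species))
    return pairs


def fit_scaling(sim_values, data_means, data_sems=None):
    """Weighted least-squares affine scaling of one species.

    Finds (alpha, beta) minimizing sum(((alpha + beta*x - e)/(e*sigma))^2)
    over all supplied points (pool conditions before calling to keep the
    scaling condition-independent).  A constant trajectory against
    nonconstant data leaves beta unidentifiable: flagged with a warning,
    beta pinned at 1.  beta is clamped positive.

    Returns (alpha, beta, degenerate_flag).
    """
    x = np.asarray(sim_values, dtype=float)
    e = np.asarray(data_means, dtype=float)
    if x.size != e.size or x.size < 2:
        raise ValueError("need matched arrays with at least 2 points")
    sig = (np.ones_like(e) if data_sems is None
           else np.asarray(data_sems, dtype=float))
    w = 1.0 / (e * sig)
    if np.ptp(x) <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        degenerate = np.ptp(e) > 1e-12 * max(1.0, float(np.max(np.abs(e))))
        if degenerate:
            warnings.warn("constant trajectory against nonconstant data: "
                          "scaling gain is unidentifiable")
        beta = 1.0
        alpha = float(np.average(e - beta * x, weights=w ** 2))
        return alpha, beta, degenerate
    A = np.vstack([np.ones_like(x), x]).T * w[:, None]
    coef, *_ = np.linalg.lstsq(A, e * w, rcond=None)
    alpha, beta = float(coef[0]), float(coef[1])
    if beta <= 0:
        beta = 1e-6
        alpha = float(np.average(e - beta * x, weights=w ** 2))
    return alpha, beta, False


def _simulate_plan(model: Il4SystemsModel, params: dict, pairs, dataset,
                   t_end: float = 120.0):
    """Simulate each needed condition once; return {(cond, species): sim values}."""
    conds = sorted({c for c, _ in pairs})
    # conditions sharing a baseline ROS share one pre-equilibration
    ss_cache: dict[float, np.ndarray] = {}
    out = {}
    for cname in conds:
        condition = STANDARD_CONDITIONS[cname]
        a = model.ros_profile_for(condition).a
        try:
            if a not in ss_cache:
                ss_cache[a] = model.steady_state(a, parameters=params)
            df = model.simulate_condition(condition, t_end=t_end,
                                          parameters=params, y0=ss_cache[a])
        except (RuntimeError, ValueError) as err:
            raise SimulationFailure(str(err)) from err
        for c, species in pairs:
            if c != cname:
                continue
            t, _, _ = dataset.series(c, species)
            sim = np.interp(t, df["time_min"].to_numpy(),
                            df[species].to_numpy())
            out[(c, species)] = sim
    return out


def _profiled_scaling(sims, dataset, pairs) -> ObservationScaling:
    alpha, beta = {}, {}
    for species in sorted({s for _, s in pairs}):
        xs, es, ss = [], [], []
        for c, s in pairs:
            if s != species:
                continue
            t, e, sig = dataset.series(c, s)
            xs.append(sims[(c, s)])
            es.append(e)
            ss.append(sig)
        a, b, _ = fit_scaling(np.concatenate(xs), np.concatenate(es),
                              np.concatenate(ss))
        alpha[species], beta[species] = a, b
    return ObservationScaling(alpha=alpha, beta=beta)


def objective(params: dict, dataset: ExperimentDataset, model: Il4SystemsModel,
              scaling: ObservationScaling | None = None, plan=None,
              return_scaling: bool = False):
    """Weighted squared-error objective over the training plan.

    When ``scaling`` is None the per-species affine scalings are
    profiled out by weighted least squares before the error is summed.
    Raises SimulationFailure when the model cannot be integrated.
    """
    dataset.validate_for_fitting()
    pairs = _plan_from_dataset(dataset, plan)
    if not pairs:
        raise ValueError("dataset contains no series matching the fit plan")
    full = dict(model.parameters)
    full.update(params)
    sims = _simulate_plan(model, full, pairs, dataset)
    if scaling is None:
        scaling = _profiled_scaling(sims, dataset, pairs)
    total = 0.0
    for (c, s), sim in sims.items():
        t, e, sig = dataset.series(c, s)
        y = scaling.apply(s, sim)
        total += float(np.sum(((y - e) / (e * sig)) ** 2))
    if return_scaling:
        return total, scaling
    return total


@dataclass(frozen=True)
class EsConfig:
    """(mu + lambda) evolutionary-strategy settings (log10 parameter space)."""

    population: int = 40          # offspring per generation (lambda)
    parents: int = 8              # retained parents (mu)
    step: float = 0.15            # mutation step, log10 units
    hyper_trigger: int = 15       # stagnant generations before hyper-mutation
    hyper_factor: float = 10.0    # step magnification during hyper-mutation
    hyper_length: int = 3         # generations the magnified step lasts
    max_generations: int = 100
    seed: int = 0
    bound_decades: float = 1.5    # reflecting bounds: +/- decades around start

    def __post_init__(self):
        if min(self.population, self.parents, self.hyper_trigger,
               self.hyper_length, self.max_generations) < 1:
            raise ValueError("all counts must be positive")
        if self.step <= 0 or self.hyper_factor <= 0 or self.bound_decades <= 0:
            raise ValueError("step sizes and bounds must be positive")
        if self.parents > self.population:
            raise ValueError("parents cannot exceed population")


@dataclass
class FitResult:
    best_params: dict
    best_objective: float
    trace: list = field(default_factory=list)  # best-ever objective per generation
    scaling: ObservationScaling | None = None
    n_evaluations: int = 0
    n_failures: int = 0


def _reflect(x, lo, hi):
    rng = hi - lo
    y = np.mod(x - lo, 2 * rng)
    y = np.where(y > rng, 2 * rng - y, y)
    return lo + y


def evolution_strategy(fn, x0: np.ndarray, config: EsConfig,
                       bounds: tuple[np.ndarray, np.ndarray] | None = None):
    """Minimize fn(x) by a (mu + lambda) ES with hyper-mutation.

    ``x0`` and bounds are in the (log10) search space.  ``fn`` may raise
    SimulationFailure; failed candidates receive a penalty of 10x the
    worst feasible objective seen so far.  Returns (x_best, f_best,
    trace, n_evals, n_failures).
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    lo, hi = (bounds if bounds is not None
              else (x0 - config.bound_decades, x0 + config.bound_decades))
    rng = np.random.default_rng(config.seed)
    worst_feasible = 1.0
    n_evals = 0
    n_failures = 0

    def evaluate(x):
        nonlocal worst_feasible, n_evals, n_failures
        n_evals += 1
        try:
            f = float(fn(x))
        except SimulationFailure:
            n_failures += 1
            return 10.0 * worst_feasible, False
        if not np.isfinite(f):
            n_failures += 1
            return 10.0 * worst_feasible, False
        worst_feasible = max(worst_feasible, f)
        return f, True

    f0, ok = evaluate(x0)
    parents = [(f0, x0)]
    if not ok:
        raise SimulationFailure("objective failed at the starting point")
    best_f, best_x = f0, x0.copy()
    trace = [best_f]
    stagnant = 0
    hyper_left = 0
    for _ in range(config.max_generations):
        step = config.step * (config.hyper_factor if hyper_left > 0 else 1.0)
        hyper_left = max(0, hyper_left - 1)
        offspring = []
        any_ok = False
        for i in range(config.population):
            parent = parents[i % len(parents)][1]
            child = _reflect(parent + rng.normal(0.0, step, size=d), lo, hi)
            f, ok = evaluate(child)
            any_ok = any_ok or ok
            offspring.append((f, child))
        if not any_ok:
            raise SimulationFailure(
                "every candidate simulation failed in one generation")
        pool = parents + offspring
        pool.sort(key=lambda t: t[0])
        parents = pool[:config.parents]
        if parents[0][0] < best_f - 1e-12:
            best_f, best_x = parents[0][0], parents[0][1].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= config.hyper_trigger and hyper_left == 0:
                hyper_left = config.hyper_length
                stagnant = 0
        trace.append(best_f)
    return best_x, best_f, trace, n_evals, n_failures


def es_fit(model: Il4SystemsModel, dataset: ExperimentDataset,
           config: EsConfig, free_parameters=None, plan=None,
           scaling: ObservationScaling | None = None) -> FitResult:
    """Fit model rate constants to a dataset; returns best params and trace."""
    free = list(free_parameters or DEFAULT_FREE_PARAMETERS)
    x0 = np.log10([model.parameters[k] for k in free])

    def fn(x):
        params = {k: 10.0 ** v for k, v in zip(free, x)}
        return objective(params, dataset, model, scaling=scaling, plan=plan)

    x_best, f_best, trace, n_evals, n_failures = evolution_strategy(
        fn, x0, config)
    best_params = {k: 10.0 ** v for k, v in zip(free, x_best)}
    _, final_scaling = objective(best_params, dataset, model, scaling=scaling,
                                 plan=plan, return_scaling=True)
    return FitResult(best_params=best_params, best_objective=f_best,
                     trace=trace, scaling=final_scaling,
                     n_evaluations=n_evals, n_failures=n_failures)
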
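"""Synthetic flow-cytometry-style datasets for the IL-4 redox pipeline.

The generator simulates the detailed systems model at a vetted "truth"
parameterization across the panel of treatment conditions, applies
per-species affine observation scalings, and emulates replicate
flow-cytometry measurements with multiplicative Gaussian noise (MFIs
are positive and scale-dependent), reporting mean and SEM per point
exactly as a normalized-MFI table would.  Cumulative dye-oxidation
(DCFDA) curves are the time integral of the condition's instantaneous
ROS truth, so the ROS-inference stage can be exercised end to end.

The noiseless pSTAT6 truth under IL-4 must show exactly two distinct
peaks with the first by 25 min and the second after it; generation
fails loudly otherwise rather than silently emitting a dataset the
downstream screen could not be expected to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExperimentDataset
from .peaks import extract_features
from .systems_model import (STANDARD_CONDITIONS, Il4SystemsModel,
                            ObservationScaling)

__all__ = ["GeneratorSpec", "generate_dataset", "generate_dye_curves",
           "normalize_mfi", "DEFAULT_TIME_GRID", "DEFAULT_BETA"]

DEFAULT_TIME_GRID = (0, 5, 10, 15, 20, 25, 30, 45, 60, 90, 120)

DATASET_CONDITIONS = ("untreated", "IL4", "IL4+DPI", "IL4+H2O2",
                      "IL4+CHX", "IL4+MG132")
DATASET_SPECIES = ("pSTAT6", "STAT6", "SOCS3")

# Observation gains (normalized-MFI units per model au); offsets are set so
# the untreated (basal) readout sits at 1.0, matching the normalization of
# measured MFIs by the untreated sample.
DEFAULT_BETA = {"pSTAT6": 4.5, "STAT6": 0.3, "SOCS3": 1.0}

# Raw-MFI emulation constants per species: (background MFI, untreated MFI).
_RAW_MFI = {"pSTAT6": (120.0, 480.0), "STAT6": (80.0, 2100.0),
            "SOCS3": (150.0, 520.0)}


def normalize_mfi(mfi_sample: float, mfi_bk: float, mfi_untreat: float) -> float:
    """Background-corrected MFI normalized by the untreated sample."""
    denom = mfi_untreat - mfi_bk
    if denom == 0:
        raise ZeroDivisionError("untreated MFI equals background MFI")
    return (mfi_sample - mfi_bk) / denom


@dataclass
class GeneratorSpec:
    """Settings of the synthetic-data generator.

    ``noise_cv`` is the coefficient of variation of replicate
    measurements; replicate count defaults to three
    experiments per point.
    """

    truth_params: dict = field(default_factory=dict)
    scaling: ObservationScaling | None = None
    noise_cv: float = 0.05
    n_replicates: int = 3
    time_grid: tuple = DEFAULT_TIME_GRID
    conditions: tuple = DATASET_CONDITIONS
    seed: int = 0
    sem_floor: float = 1e-6

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        grid = tuple(float(t) for t in self.time_grid)
        if min(grid) < 0 or max(grid) > 120:
            raise ValueError("time grid must lie within [0, 120] min")
        self.time_grid = grid

    def build_model(self) -> Il4SystemsModel:
        return Il4SystemsModel(parameters=self.truth_params)


class TwoPeakConstraintError(RuntimeError):
    pass


def _default_scaling(model: Il4SystemsModel, basal: dict[str, float]
                     ) -> ObservationScaling:
    beta = dict(DEFAULT_BETA)
    alpha = {sp: 1.0 - beta[sp] * basal[sp] for sp in beta}
    return ObservationScaling(alpha=alpha, beta=beta)


def _check_two_peaks(df: pd.DataFrame) -> None:
    feats = extract_features(df["pSTAT6"].to_numpy(),
                             df["time_min"].to_numpy())
    if feats.n_peaks != 2:
        raise TwoPeakConstraintError(
            f"truth pSTAT6 trace has {feats.n_peaks} distinct peaks, not 2; "
            "re-parameterize the truth model")
    if not (0.0 < feats.t1 <= 25.0 and 25.0 < feats.t2 <= 120.0):
        raise TwoPeakConstraintError(
            f"truth peak times t1={feats.t1:.1f}, t2={feats.t2:.1f} min fall "
            "outside the required (0,25] / (25,120] windows")


def generate_dataset(spec: GeneratorSpec) -> ExperimentDataset:
    """Simulate, scale and noise the full per-condition dataset.

    The returned dataset carries an extra ``raw_mfi`` attribute: a table
    of emulated (sample, background, untreated) MFI triples consistent
    with the normalized means via the standard MFI normalization.
    """
    model = spec.build_model()
    rng = np.random.default_rng(spec.seed)
    trajs: dict[str, pd.DataFrame] = {}
    ss_cache: dict[float, np.ndarray] = {}
    for cname in spec.conditions:
        cond = STANDARD_CONDITIONS[cname]
        a = model.ros_profile_for(cond).a
        if a not in ss_cache:
            ss_cache[a] = model.steady_state(a)
        trajs[cname] = model.simulate_condition(cond, y0=ss_cache[a])
    if "IL4" in trajs:
        _check_two_peaks(trajs["IL4"])

    basal_state = model.steady_state(model.ros_il4.a)
    idx = model.system._index
    basal = {}
    from .systems_model import OBSERVABLE_SPECIES
    for obs, members in OBSERVABLE_SPECIES.items():
        basal[obs] = float(sum(basal_state[idx[m]] for m in members))
    scaling = spec.scaling or _default_scaling(model, basal)

    t_grid = np.array(spec.time_grid)
    rows = []
    raw_rows = []
    for cname in spec.conditions:
        df = trajs[cname]
        for species in DATASET_SPECIES:
            x = np.interp(t_grid, df["time_min"].to_numpy(),
                          df[species].to_numpy())
            y_true = scaling.apply(species, x)
            reps = y_true[None, :] * (
                1.0 + spec.noise_cv * rng.standard_normal(
                    (spec.n_replicates, t_grid.size)))
            mean = (reps.mean(axis=0) if spec.noise_cv > 0 else y_true)
            sem = np.maximum(reps.std(axis=0, ddof=1)
                             / np.sqrt(spec.n_replicates)
                             if spec.n_replicates > 1 else
                             np.zeros_like(mean), spec.sem_floor)
            bk, untreat = _RAW_MFI[species]
            for k, t in enumerate(t_grid):
                rows.append((cname, species, t, mean[k], sem[k]))
                raw_rows.append((cname, species, t,
                                 bk + mean[k] * (untreat - bk), bk, untreat))
    table = pd.DataFrame(rows, columns=["condition", "species", "time_min",
                                        "mean", "sem"])
    dataset = ExperimentDataset(table)
    dataset.raw_mfi = pd.DataFrame(
        raw_rows, columns=["condition", "species", "time_min",
                           "mfi_sample", "mfi_bk", "mfi_untreat"])
    return dataset


def generate_dye_curves(spec: GeneratorSpec,
                        conditions=("untreated", "IL4", "IL4+DPI")
                        ) -> pd.DataFrame:
    """Cumulative DCFDA oxidation time courses per condition.

    The noiseless curve is ``dye_offset + g * integral of the truth ROS
    input``, with a shared fluorescence-per-ROS gain g = 1/b(IL-4), so
    the IL-4 curve reproduces its generating Hill shape up to a small
    linear baseline-oxidation drift.  Replicate noise as in
    generate_dataset.  Columns: condition, time_min, mean_fluorescence,
    sem.
    """
    model = spec.build_model()
    rng = np.random.default_rng(spec.seed + 17)
    g = 1.0 / model.ros_il4.b
    t_grid = np.array(spec.time_grid)
    t_dense = np.linspace(0.0, 120.0, 1201)
    rows = []
    for cname in conditions:
        cond = STANDARD_CONDITIONS[cname]
        profile = model.ros_profile_for(cond)
        u = np.array([profile(t) for t in t_dense])
        cum_dense = np.concatenate([[0.0], np.cumsum(
            0.5 * (u[1:] + u[:-1]) * np.diff(t_dense))])
        offset = (profile.curve.offset if profile.curve is not None else 0.05)
        y_true = offset + g * np.interp(t_grid, t_dense, cum_dense)
        reps = y_true[None, :] * (
            1.0 + spec.noise_cv * rng.standard_normal(
                (spec.n_replicates, t_grid.size)))
        mean = reps.mean(axis=0) if spec.noise_cv > 0 else y_true
        sem = np.maximum(reps.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates)
                         if spec.n_replicates > 1 else np.zeros_like(mean),
                         spec.sem_floor)
        for k, t in enumerate(t_grid):
            rows.append((cname, t, mean[k], sem[k]))
    return pd.DataFrame(rows, columns=["condition", "time_min",
                                       "mean_fluorescence", "sem"])
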
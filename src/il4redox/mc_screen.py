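"""Monte-Carlo topology screening on two-peak pSTAT6 dynamics.

For each network topology, rate constants are sampled log-uniformly in a
box spanning a fixed number of decades around a center vector, the
reduced model is integrated over 0-120 min, and the total-pSTAT6 trace
(cytosolic + nuclear phosphorylated STAT6) is classified by its number
of distinct peaks.  A topology passes the qualitative screen when the
fraction of two-peak traces exceeds a threshold (0.1% by default, i.e.
more than 50 of 50,000 draws at full scale).  Two-peak traces also feed
a quantitative comparison: smoothed bivariate feature densities
evaluated at the features of the measured curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from ._fastsim import STATUS_OK, simulate_fast
from .network_library import NetworkTopology, build_reduced_model
from .peaks import (DEFAULT_PROMINENCE_FRAC, PeakFeatureSet, extract_features,
                    find_distinct_maxima)

__all__ = ["ParameterEnsembleSpec", "TopologyScreenResult", "SelectionResult",
           "sample_parameters", "run_mc_screen", "feature_match",
           "load_default_centers", "center_for"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.001  # pass requires fraction of two-peak traces > this


def load_default_centers() -> dict:
    """Packaged screen centers: shared vector + per-cycling-mode overrides."""
    import importlib.resources as resources

    import yaml

    text = (resources.files("il4redox") / "data" / "mc_centers.yaml").read_text()
    return yaml.safe_load(text)


def center_for(topology: NetworkTopology, centers: dict | None = None
               ) -> dict[str, float]:
    """Center parameter vector for one topology from a centers config."""
    cfg = centers if centers is not None else load_default_centers()
    if "shared" not in cfg:  # plain parameter dict
        return dict(cfg)
    center = dict(cfg["shared"])
    if not topology.stat_cycling_phospho_dependent:
        center.update(cfg.get("independent_cycling_overrides", {}))
    return center


@dataclass(frozen=True)
class ParameterEnsembleSpec:
    """Log-uniform sampling box around a center parameter vector.

    ``span_decades`` is the half-width in log10 units; the default 0.5
    makes the box span one order of magnitude in total
    (center / sqrt(10) to center * sqrt(10)).
    """

    center: dict[str, float]
    span_decades: float = 0.5
    n_samples: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if not self.center:
            raise ValueError("empty parameter center")
        for k, v in self.center.items():
            if not v > 0:
                raise ValueError(f"center entry {k!r} must be positive (got {v})")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.span_decades < 0:
            raise ValueError("span_decades must be nonnegative")


def sample_parameters(spec: ParameterEnsembleSpec) -> tuple[list[str], np.ndarray]:
    """Draw the ensemble; returns (parameter names, array n_samples x d).

    Each coordinate is independent log10-uniform on
    [log10(center) - span, log10(center) + span]; a fixed seed fixes the
    draws.
    """
    names = list(spec.center)
    center = np.log10(np.array([spec.center[k] for k in names]))
    rng = np.random.default_rng(spec.seed)
    lo = center - spec.span_decades
    hi = center + spec.span_decades
    draws = rng.uniform(lo, hi, size=(spec.n_samples, len(names)))
    return names, 10.0 ** draws


@dataclass
class TopologyScreenResult:
    topology: NetworkTopology
    n_samples: int
    two_peak_count: int
    n_failures: int
    peak_counts: np.ndarray            # per-sample number of distinct maxima
    features: list[PeakFeatureSet]     # one per two-peak trace

    @property
    def fraction(self) -> float:
        return self.two_peak_count / self.n_samples

    def passes(self, threshold: float = DEFAULT_THRESHOLD) -> bool:
        return self.fraction > threshold

    def feature_arrays(self) -> dict[str, np.ndarray]:
        rh = np.array([f.ratio_heights for f in self.features], dtype=float)
        sep = np.array([f.separation for f in self.features], dtype=float)
        rf = np.array([f.ratio_final_h1 for f in self.features], dtype=float)
        return {"ratio_heights": rh, "separation": sep, "ratio_final_h1": rf}


@dataclass
class SelectionResult:
    """Per-topology screen outcomes, keyed by topology label."""

    threshold: float
    per_topology: dict[str, TopologyScreenResult] = field(default_factory=dict)

    def summary(self):
        import pandas as pd

        rows = []
        for label, r in self.per_topology.items():
            t = r.topology
            rows.append({
                "topology": label,
                "ptp_oxidation": t.ptp_oxidation,
                "jak_oxidation": t.jak_oxidation,
                "ros_ptp_shuttling": t.ros_ptp_shuttling,
                "phospho_dependent_cycling": t.stat_cycling_phospho_dependent,
                "n_samples": r.n_samples,
                "two_peak_count": r.two_peak_count,
                "fraction": r.fraction,
                "passes": r.passes(self.threshold),
                "integration_failures": r.n_failures,
            })
        return pd.DataFrame(rows)


def _total_pstat6(system, Y):
    idx = system._index
    total = Y[:, idx["pS_c"]].copy()
    if "pS_n" in idx:
        total += Y[:, idx["pS_n"]]
    return total


def screen_topology(topology: NetworkTopology, spec: ParameterEnsembleSpec,
                    t_end: float = 120.0, dt: float = 0.5,
                    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                    rtol: float = 1e-6, atol: float = 1e-9,
                    ) -> TopologyScreenResult:
    """Monte-Carlo peak-count screen of one topology.

    Integration failures are logged and counted as non-two-peak traces;
    the ensemble never aborts on a bad parameter draw.
    """
    system = build_reduced_model(topology, parameters=spec.center)
    names, samples = sample_parameters(spec)
    rate_names = [r.rate for r in system.reactions]
    name_to_col = {n: j for j, n in enumerate(names)}
    cols = []
    for rn in rate_names:
        if rn not in name_to_col:
            raise KeyError(f"center vector missing rate constant {rn!r}")
        cols.append(name_to_col[rn])
    cols = np.array(cols, dtype=np.intp)

    N, ridx, rptr, _, _, _, _ = system._compile()
    y0 = system.y0()
    t_grid = np.arange(0.0, t_end + dt / 2, dt)

    peak_counts = np.zeros(spec.n_samples, dtype=int)
    features: list[PeakFeatureSet] = []
    n_failures = 0
    from ._fastsim import integrate_mass_action, _A, _B5, _C, _E
    for s in range(spec.n_samples):
        kvec = samples[s, cols]
        Y, status = integrate_mass_action(kvec, ridx, rptr, N, y0, t_grid,
                                          rtol, atol, 200_000, _A, _C, _B5, _E)
        if status != STATUS_OK or not np.all(np.isfinite(Y)):
            n_failures += 1
            peak_counts[s] = -1
            continue
        trace = _total_pstat6(system, Y)
        try:
            idx = find_distinct_maxima(trace, prominence_frac)
        except ValueError:
            n_failures += 1
            peak_counts[s] = -1
            continue
        peak_counts[s] = len(idx)
        if len(idx) == 2:
            features.append(extract_features(trace, t_grid, prominence_frac))
    if n_failures:
        logger.warning("%s: %d/%d integrations failed (counted as non-two-peak)",
                       topology.label, n_failures, spec.n_samples)
    return TopologyScreenResult(
        topology=topology, n_samples=spec.n_samples,
        two_peak_count=int(np.sum(peak_counts == 2)),
        n_failures=n_failures, peak_counts=peak_counts, features=features)


def run_mc_screen(topologies, centers: dict | None = None,
                  n_samples: int = 50_000, seed: int = 0,
                  span_decades: float = 0.5,
                  threshold: float = DEFAULT_THRESHOLD,
                  **kwargs) -> SelectionResult:
    """Screen a list of topologies.

    ``centers`` is the packaged centers config by default; it may also be
    a plain parameter dict shared by all topologies, a config with
    ``shared``/``independent_cycling_overrides`` sections, or a mapping
    label -> center dict.  Each topology gets a deterministic
    per-topology seed derived from ``seed``.
    """
    result = SelectionResult(threshold=threshold)
    if centers is None:
        centers = load_default_centers()
    for i, topo in enumerate(topologies):
        if isinstance(centers, dict) and topo.label in centers:
            center = dict(centers[topo.label])
        else:
            center = center_for(topo, centers)
        system = build_reduced_model(topo)
        used = {r.rate for r in system.reactions}
        center = {k: v for k, v in center.items() if k in used}
        spec = ParameterEnsembleSpec(center=center, span_decades=span_decades,
                                     n_samples=n_samples, seed=seed + 1000 * i)
        result.per_topology[topo.label] = screen_topology(topo, spec, **kwargs)
    return result


def feature_match(result: TopologyScreenResult, reference: PeakFeatureSet,
                  min_traces: int = 5) -> float:
    """Match score of a topology's two-peak feature cloud to a reference.

    Two Gaussian-kernel bivariate densities are formed over
    (ratio_heights, separation) and (ratio_heights, ratio_final_h1);
    each is evaluated at the reference point and normalized by its own
    maximum over the sample cloud; the score is the mean of the two.
    Returns 0 when the topology produced too few two-peak traces.
    """
    if reference.n_peaks < 2:
        raise ValueError("reference must be a two-peak feature set")
    arrs = result.feature_arrays()
    if len(result.features) < min_traces:
        return 0.0
    scores = []
    for ykey, ref_y in (("separation", reference.separation),
                        ("ratio_final_h1", reference.ratio_final_h1)):
        pts = np.vstack([arrs["ratio_heights"], arrs[ykey]])
        try:
            kde = gaussian_kde(pts)
        except np.linalg.LinAlgError:
            return 0.0
        dens_max = float(np.max(kde(pts)))
        if dens_max <= 0:
            return 0.0
        ref_pt = np.array([[reference.ratio_heights], [ref_y]])
        scores.append(float(kde(ref_pt)[0]) / dens_max)
    return float(np.mean(scores))
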
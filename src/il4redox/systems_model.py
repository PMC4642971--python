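"""Detailed mass-action systems model of IL-4/STAT6 signaling.

The model tracks ligand-induced activation of a lumped receptor complex
(receptor chains plus constitutively bound JAKs), STAT6 phosphorylation,
phospho-dependent nuclear-cytosolic cycling, SOCS negative feedback,
STAT6 turnover, and ROS-driven reversible oxidation of two protein
tyrosine phosphatases: P1 (dephosphorylates cytosolic pSTAT6) and P2
(deactivates the receptor complex).  Intracellular ROS enter as a
measured input profile (see :mod:`il4redox.ros_input`) rather than as a
mechanistic Nox/clearance network; oxidized phosphatases are re-reduced
first order (constant cellular reducing capacity), and the nuclear
compartment carries no oxidation reactions.

Phosphorylation/dephosphorylation are written as two-step mass action
with explicit enzyme-substrate complexes.  SOCS production saturates in
active (phosphorylated) STAT6; SOCS binds the active receptor and makes
it catalytically inert, and receptor dephosphorylation releases SOCS.
Pharmacological conditions map onto the model as: CHX zeroes the protein
synthesis fluxes (STAT6 source, SOCS production), MG132 zeroes
proteasomal pSTAT6 degradation, DPI swaps in the DPI-fit ROS profile,
and exogenous H2O2 adds an exponentially decaying ROS bolus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .reaction import ReactionSystem, SaturatingProduction, parse_reaction
from .ros_input import HillCurve, RosProfile, add_h2o2_bolus, make_ros_profile

__all__ = ["Condition", "ObservationScaling", "Il4SystemsModel",
           "DEFAULT_SYSTEMS_PARAMETERS", "DEFAULT_INITIAL_STATE",
           "default_il4_ros_profile", "default_dpi_ros_profile",
           "build_systems_network", "observe", "OBSERVABLE_SPECIES"]

SYSTEMS_SPECIES = [
    "IL4", "R", "Ra", "SOCS", "RaSOCS",
    "P1", "P1ox", "P2", "P2ox",
    "S_c", "pS_c", "S_n", "pS_n",
    "C_RaS", "C_P1pS", "C_P2Ra",
]

_COMPARTMENT = {s: ("nucleus" if s.endswith("_n") else "cytosol")
                for s in SYSTEMS_SPECIES}

# Rates in 1/min (or 1/(au*min) for bimolecular steps); amounts in model au.
# Under the reporting convention 1 ROS unit ~ 1 nM, the phosphatase
# oxidation constant 0.12 /(unit*min) corresponds to ~2e6 M^-1 s^-1.
DEFAULT_SYSTEMS_PARAMETERS = {
    "k_act": 1.8,        # IL-4-driven receptor activation (ligand clamped)
    "k_basal": 0.00292,  # ligand-independent basal receptor activation
    "kon_phos": 1.25,    # Ra + S_c binding
    "kcat_phos": 10.0,   # catalytic release of pS_c
    "kon_p1": 13.1,      # P1 + pS_c binding
    "kcat_p1": 45.7,
    "kon_p2": 161.0,     # P2 + Ra binding
    "kcat_p2": 2.83,
    "k_socs_on": 18.1,
    "k_socs_off": 0.0986,
    "k_socs_dp": 17.3,   # P2-mediated dephosphorylation of Ra.SOCS (releases SOCS)
    "v_socs": 0.789,     # max SOCS production rate (au/min)
    "km_socs": 0.441,    # half-saturating active STAT6 (au)
    "k_socs_deg": 0.36,
    "k_stat_syn": 0.003,     # STAT6 synthesis (au/min)
    "k_stat_deg": 0.00445,   # proteasomal pSTAT6 degradation (MG132-sensitive)
    "k_stat_deg_u": 0.001,   # slow constitutive turnover of unphosphorylated STAT6
    "k_in": 0.587,       # pSTAT6 nuclear import
    "k_out": 0.172,      # STAT6 nuclear export
    "k_dpn": 0.228,      # nuclear pSTAT6 dephosphorylation (lumped nuclear PTP)
    "k_ox1": 0.12,       # P1 oxidation per ROS unit
    "k_red1": 0.154,     # P1ox reduction
    "k_ox2": 0.12,       # P2 oxidation per ROS unit
    "k_red2": 0.154,     # P2ox reduction
}

DEFAULT_INITIAL_STATE = {
    "R": 1.0,
    "S_c": 3.0,
    "P1": 1.13,
    "P2": 1.33,
}

# Default "truth" dye-oxidation curves (normalized fluorescence units) from
# which the default ROS inputs derive; the IL-4 curve's derivative peaks
# near 20 min and the profile peaks near 100 ROS units.
DEFAULT_IL4_DYE_CURVE = HillCurve(fmax=3.0, k_half=27.0, n_hill=2.6, offset=0.6)
DEFAULT_DPI_DYE_CURVE = HillCurve(fmax=0.8, k_half=30.0, n_hill=2.2, offset=0.15)
DEFAULT_IL4_BASELINE_A = 4.0
DEFAULT_DPI_BASELINE_A = 0.6
DEFAULT_H2O2_BOLUS = (100.0, 0.15)  # amplitude (ROS units), decay (1/min)


def _profile_b_for_peak(curve: HillCurve, a: float, peak: float = 100.0) -> float:
    t = np.linspace(0.0, 120.0, 4801)
    dmax = float(np.max(curve.derivative(t)))
    return (peak - a) / dmax


def default_il4_ros_profile() -> RosProfile:
    """IL-4 input: baseline 4 units, transient peaking ~100 units near 20 min."""
    a = DEFAULT_IL4_BASELINE_A
    return make_ros_profile(DEFAULT_IL4_DYE_CURVE, a,
                            _profile_b_for_peak(DEFAULT_IL4_DYE_CURVE, a, 100.0))


def default_dpi_ros_profile() -> RosProfile:
    """DPI-pretreatment input: lower baseline and strongly suppressed transient."""
    a = DEFAULT_DPI_BASELINE_A
    return make_ros_profile(DEFAULT_DPI_DYE_CURVE, a,
                            _profile_b_for_peak(DEFAULT_DPI_DYE_CURVE, a, 2.5))


class _InputHolder:
    """Mutable callable wrapper so the ROS input can be swapped per condition."""

    def __init__(self, fn=None):
        self.fn = fn if fn is not None else (lambda t: 0.0)

    def __call__(self, t):
        return self.fn(t)


_REACTIONS = [
    # receptor activation (ligand binding + complex assembly collapsed; IL4 clamped)
    ("IL4 + R -> IL4 + Ra @ k_act", ()),
    ("R -> Ra @ k_basal", ()),
    # STAT6 phosphorylation by active receptor (two-step)
    ("Ra + S_c -> C_RaS @ kon_phos", ()),
    ("C_RaS -> Ra + pS_c @ kcat_phos", ()),
    # P1 dephosphorylates cytosolic pSTAT6 (two-step)
    ("P1 + pS_c -> C_P1pS @ kon_p1", ()),
    ("C_P1pS -> P1 + S_c @ kcat_p1", ()),
    # P2 deactivates the receptor complex (two-step)
    ("P2 + Ra -> C_P2Ra @ kon_p2", ()),
    ("C_P2Ra -> P2 + R @ kcat_p2", ()),
    # SOCS feedback: binding inactivates Ra; dephosphorylation releases SOCS
    ("Ra + SOCS -> RaSOCS @ k_socs_on", ()),
    ("RaSOCS -> Ra + SOCS @ k_socs_off", ()),
    ("P2 + RaSOCS -> P2 + R + SOCS @ k_socs_dp", ()),
    ("SOCS -> 0 @ k_socs_deg", ()),
    # STAT6 turnover
    ("0 -> S_c @ k_stat_syn", ()),
    ("pS_c -> 0 @ k_stat_deg", ()),
    ("S_c -> 0 @ k_stat_deg_u", ()),
    # phospho-dependent nuclear-cytosolic cycling
    ("pS_c -> pS_n @ k_in", ()),
    ("S_n -> S_c @ k_out", ()),
    ("pS_n -> S_n @ k_dpn", ()),
    # ROS-driven reversible phosphatase oxidation (cytosol only)
    ("P1 -> P1ox @ k_ox1", ("ROS",)),
    ("P1ox -> P1 @ k_red1", ()),
    ("P2 -> P2ox @ k_ox2", ("ROS",)),
    ("P2ox -> P2 @ k_red2", ()),
]


def build_systems_network(ros_input, parameters=None, initial_state=None
                          ) -> ReactionSystem:
    """Assemble the detailed model as a ReactionSystem with a ROS input."""
    params = dict(DEFAULT_SYSTEMS_PARAMETERS)
    if parameters:
        params.update(parameters)
    init = dict(DEFAULT_INITIAL_STATE if initial_state is None else initial_state)
    return ReactionSystem(
        species=list(SYSTEMS_SPECIES),
        reactions=[parse_reaction(text, mods) for text, mods in _REACTIONS],
        parameters=params,
        initial_state=init,
        compartments=dict(_COMPARTMENT),
        constant_species=frozenset({"IL4"}),
        inputs={"ROS": ros_input},
        saturating=[SaturatingProduction("SOCS", "v_socs", "km_socs",
                                         ("pS_c", "pS_n"))],
        name="il4-systems",
    )


@dataclass(frozen=True)
class Condition:
    """One simulated treatment of IL-4-responsive cells."""

    name: str = "IL4"
    il4_dose: float = 1.0          # 1.0 ~ 100 ng/ml saturating dose
    dpi: bool = False
    h2o2_bolus: tuple[float, float] | None = None  # (amplitude, decay 1/min)
    chx: bool = False
    mg132: bool = False


STANDARD_CONDITIONS = {
    "untreated": Condition("untreated", il4_dose=0.0),
    "IL4": Condition("IL4"),
    "IL4+DPI": Condition("IL4+DPI", dpi=True),
    "IL4+H2O2": Condition("IL4+H2O2", h2o2_bolus=DEFAULT_H2O2_BOLUS),
    "H2O2": Condition("H2O2", il4_dose=0.0, h2o2_bolus=DEFAULT_H2O2_BOLUS),
    "IL4+CHX": Condition("IL4+CHX", chx=True),
    "IL4+MG132": Condition("IL4+MG132", mg132=True),
}

OBSERVABLE_SPECIES = {
    # measured readout -> model species summed into it (complex-bound and
    # nuclear forms are seen by the antibody just like free cytosolic ones)
    "pSTAT6": ("pS_c", "pS_n", "C_P1pS"),
    "STAT6": ("S_c", "pS_c", "S_n", "pS_n", "C_RaS", "C_P1pS"),
    "SOCS3": ("SOCS", "RaSOCS"),
}


@dataclass(frozen=True)
class ObservationScaling:
    """Condition-independent affine map model au -> MFI: y = alpha + beta * x."""

    alpha: dict[str, float]
    beta: dict[str, float]

    def __post_init__(self):
        for sp, b in self.beta.items():
            if b <= 0:
                raise ValueError(f"beta for {sp!r} must be positive")

    def apply(self, species: str, x):
        if species not in self.beta:
            raise KeyError(f"no scaling defined for species {species!r}")
        return self.alpha.get(species, 0.0) + self.beta[species] * np.asarray(x, float)


def observe(trajectory: pd.DataFrame, scaling: ObservationScaling,
            species=None) -> pd.DataFrame:
    """Affine-scale observable columns of a simulated trajectory to MFI units."""
    if species is None:
        species = [s for s in trajectory.columns if s in scaling.beta]
    out = pd.DataFrame({"time_min": trajectory["time_min"]})
    for sp in species:
        out[sp] = scaling.apply(sp, trajectory[sp].to_numpy())
    return out


class SteadyStateError(RuntimeError):
    pass


class Il4SystemsModel:
    """Detailed IL-4 model bound to ROS input profiles and parameters."""

    def __init__(self, parameters: dict[str, float] | None = None,
                 ros_il4: RosProfile | None = None,
                 ros_dpi: RosProfile | None = None,
                 initial_state: dict[str, float] | None = None,
                 rtol: float = 1e-6, atol: float = 1e-9):
        self.parameters = dict(DEFAULT_SYSTEMS_PARAMETERS)
        if parameters:
            self.parameters.update(parameters)
        self.ros_il4 = ros_il4 if ros_il4 is not None else default_il4_ros_profile()
        self.ros_dpi = ros_dpi if ros_dpi is not None else default_dpi_ros_profile()
        self._input = _InputHolder()
        self.system = build_systems_network(self._input, self.parameters,
                                            initial_state)
        self.rtol = rtol
        self.atol = atol

    def with_parameters(self, **updates) -> "Il4SystemsModel":
        p = dict(self.parameters)
        p.update(updates)
        return Il4SystemsModel(parameters=p, ros_il4=self.ros_il4,
                               ros_dpi=self.ros_dpi,
                               initial_state=self.system.initial_state,
                               rtol=self.rtol, atol=self.atol)

    # -- ROS input per condition ----------------------------------------------

    def ros_profile_for(self, condition: Condition) -> RosProfile:
        if condition.dpi:
            base = self.ros_dpi
        elif condition.il4_dose > 0:
            base = self.ros_il4
        else:
            base = RosProfile(a=self.ros_il4.a, b=0.0)  # resting cells: baseline only
        if condition.h2o2_bolus is not None:
            amp, dec = condition.h2o2_bolus
            base = add_h2o2_bolus(base, amp, dec)
        return base

    # -- steady state ----------------------------------------------------------

    def steady_state(self, baseline_ros: float, parameters=None,
                     horizon: float = 1e4, max_horizon: float = 1e6,
                     tol: float = 1e-9) -> np.ndarray:
        """Pre-stimulus state: IL4 = 0, constant ROS = a, integrated to rest.

        Convergence requires the scaled RHS norm to fall below ``tol``;
        the integration horizon doubles (up to ``max_horizon``) until it
        does, else a SteadyStateError is raised.
        """
        if baseline_ros < 0:
            raise ValueError("baseline ROS must be nonnegative")
        params = dict(self.parameters if parameters is None else parameters)
        self._input.fn = lambda t: baseline_ros
        y0 = self.system.y0()
        idx = self.system._index
        y0[idx["IL4"]] = 0.0
        rhs = self.system.make_rhs(params)
        h = horizon
        y = y0
        while True:
            sol = self.system.simulate(np.array([0.0, h / 2, h]), y0=y,
                                       parameters=params,
                                       rtol=self.rtol, atol=self.atol)
            y = sol[-1]
            dy = rhs(0.0, y)
            if float(np.max(np.abs(dy))) < tol * (1.0 + float(np.max(np.abs(y)))):
                return np.maximum(y, 0.0)
            h *= 2
            if h > max_horizon:
                raise SteadyStateError(
                    f"no steady state within horizon {max_horizon} min")

    # -- condition simulation ---------------------------------------------------

    def simulate_condition(self, condition: Condition, t_end: float = 120.0,
                           dt: float = 0.5, parameters=None,
                           y0: np.ndarray | None = None) -> pd.DataFrame:
        """Simulate one treatment; returns a tidy frame of species + observables.

        The model is pre-equilibrated at the condition's baseline ROS
        before t = 0; inhibitors (CHX/MG132) and IL-4/peroxide are
        applied at t = 0.
        """
        params = dict(self.parameters if parameters is None else parameters)
        profile = self.ros_profile_for(condition)
        if y0 is None:
            y0 = self.steady_state(profile.a, parameters=params)
        y0 = np.array(y0, dtype=float)
        if condition.chx:
            params["k_stat_syn"] = 0.0
            params["v_socs"] = 0.0
        if condition.mg132:
            params["k_stat_deg"] = 0.0
        idx = self.system._index
        y0[idx["IL4"]] = condition.il4_dose
        self._input.fn = profile
        t_grid = np.arange(0.0, t_end + dt / 2, dt)
        try:
            Y = self.system.simulate(t_grid, y0=y0, parameters=params,
                                     rtol=self.rtol, atol=self.atol)
        except RuntimeError as err:
            raise RuntimeError(
                f"simulation of condition {condition.name!r} failed: {err}") from err
        if float(np.min(Y)) < -1e3 * self.atol:
            raise RuntimeError(
                f"negative state beyond tolerance in condition {condition.name!r}")
        df = pd.DataFrame(Y, columns=self.system.species)
        df.insert(0, "time_min", t_grid)
        for obs, members in OBSERVABLE_SPECIES.items():
            df[obs] = sum(df[m] for m in members)
        df["ROS_input"] = np.array([profile(t) for t in t_grid])
        return df

    def simulate_conditions(self, conditions, **kwargs) -> dict[str, pd.DataFrame]:
        return {c.name: self.simulate_condition(c, **kwargs) for c in conditions}
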
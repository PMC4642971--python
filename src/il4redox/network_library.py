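"""Combinatorial library of reduced IL-4 signaling network topologies.

The IL-4 pathway is decomposed into a mandatory core (ligand-induced
receptor activation, STAT6 phosphorylation by the active receptor, ROS
upregulation by the active receptor, and generic PTP-mediated
dephosphorylation in both compartments) plus four optional regulatory
mechanisms:

* ``ptp_oxidation`` — reversible oxidative inactivation of the cytosolic
  phosphatase by ROS;
* ``jak_oxidation`` — reversible oxidative inactivation of the receptor
  complex (receptor-bound kinases are treated as implicit in the
  receptor species);
* ``ros_ptp_shuttling`` — ROS-driven net relocation of the nuclear
  phosphatase to the cytosol;
* ``stat_cycling_phospho_dependent`` — if set, STAT6 nuclear import is
  restricted to the phosphorylated form and export to the
  dephosphorylated form; otherwise both forms shuttle bidirectionally.

All 2^4 = 16 flag combinations define the model library.  Each topology
compiles to an elementary mass-action ODE system: sequential events such
as receptor-complex assembly or pSTAT6 dimerization are collapsed into
single reactions, and the nuclear compartment carries no oxidation
chemistry (it is the more reducing environment).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .reaction import ReactionSystem, parse_reaction

__all__ = ["NetworkTopology", "enumerate_topologies", "build_reduced_model",
           "REDUCED_SPECIES_ORDER", "DEFAULT_REDUCED_PARAMETERS",
           "DEFAULT_REDUCED_INITIAL_STATE"]

_FLAGS = ("ptp_oxidation", "jak_oxidation", "ros_ptp_shuttling",
          "stat_cycling_phospho_dependent")
_LETTER = {"ptp_oxidation": "P", "jak_oxidation": "J",
           "ros_ptp_shuttling": "S", "stat_cycling_phospho_dependent": "D"}


@dataclass(frozen=True)
class NetworkTopology:
    """Boolean mechanism flags selecting one of the 16 reduced models."""

    ptp_oxidation: bool
    jak_oxidation: bool
    ros_ptp_shuttling: bool
    stat_cycling_phospho_dependent: bool
    label: str

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.ptp_oxidation, self.jak_oxidation,
                self.ros_ptp_shuttling, self.stat_cycling_phospho_dependent)


def _label(flags: dict[str, bool]) -> str:
    letters = [_LETTER[f] for f in _FLAGS if flags[f]]
    return "+".join(letters) if letters else "core"


def enumerate_topologies() -> list[NetworkTopology]:
    """All 16 topologies, in a fixed order (binary over the four flags)."""
    out = []
    for bits in product((False, True), repeat=4):
        flags = dict(zip(_FLAGS, bits))
        out.append(NetworkTopology(label=_label(flags), **flags))
    return out


# Fixed species order for the full (all-mechanism) reduced model; each
# topology uses the subsequence of species it actually contains.
REDUCED_SPECIES_ORDER = [
    "R", "Ra", "Rox", "ROS",
    "S_c", "pS_c", "S_n", "pS_n",
    "P_c", "Pox", "P_n",
]

_COMPARTMENT = {
    "R": "cytosol", "Ra": "cytosol", "Rox": "cytosol", "ROS": "cytosol",
    "S_c": "cytosol", "pS_c": "cytosol", "S_n": "nucleus", "pS_n": "nucleus",
    "P_c": "cytosol", "Pox": "cytosol", "P_n": "nucleus",
}

# Center parameter values (per-minute rates, arbitrary amount units) shared
# by the library; see mc_screen for how Monte-Carlo ensembles sample around
# them.  Mechanism-specific constants are ignored by topologies lacking the
# mechanism.
DEFAULT_REDUCED_PARAMETERS = {
    "k_act": 0.3,          # IL-4-driven receptor activation (ligand collapsed in)
    "k_phos": 3.0,         # R* phosphorylating cytosolic STAT6
    "k_dephos_s": 6.0,     # cytosolic P dephosphorylating pSTAT6
    "k_dephos_r": 6.0,     # cytosolic P deactivating R*
    "k_dephos_n": 6.0,     # nuclear P dephosphorylating nuclear pSTAT6
    "k_ros_prod": 60.0,    # ROS production by R*
    "k_ros_clear": 0.6,    # first-order ROS clearance (constant reducing capacity)
    "k_nuc_in": 0.25,      # STAT6 nuclear import
    "k_nuc_out": 0.03,     # STAT6 nuclear export
    "k_ptp_ox": 0.02,      # P_c + ROS -> Pox
    "k_ptp_red": 0.03,     # Pox -> P_c
    "k_jak_ox": 0.02,      # R(*) + ROS -> Rox
    "k_jak_red": 0.03,     # Rox -> R
    "k_shuttle_out": 0.02, # ROS-catalyzed P_n -> P_c relocation
    "k_shuttle_in": 0.2,   # constitutive P_c -> P_n return
}

DEFAULT_REDUCED_INITIAL_STATE = {
    "R": 1.0,
    "S_c": 3.0,
    "P_c": 0.3,
    "P_n": 0.3,
}


def build_reduced_model(topology: NetworkTopology,
                        parameters: dict[str, float] | None = None,
                        initial_state: dict[str, float] | None = None,
                        ) -> ReactionSystem:
    """Compile a topology into an elementary mass-action ReactionSystem.

    ROS is a dynamic species produced catalytically by the active
    receptor and cleared first order, so unstimulated systems relax to
    zero ROS.  Unknown/invalid topologies (labels inconsistent with the
    flags) are rejected.
    """
    if not isinstance(topology, NetworkTopology):
        raise TypeError("topology must be a NetworkTopology")
    flags = dict(zip(_FLAGS, topology.flags))
    if topology.label != _label(flags):
        raise ValueError(f"topology label {topology.label!r} inconsistent with flags")

    rxns = [
        "R -> Ra @ k_act",
        "Ra + S_c -> Ra + pS_c @ k_phos",
        "P_c + pS_c -> P_c + S_c @ k_dephos_s",
        "P_c + Ra -> P_c + R @ k_dephos_r",
        "P_n + pS_n -> P_n + S_n @ k_dephos_n",
        "Ra -> Ra + ROS @ k_ros_prod",
        "ROS -> 0 @ k_ros_clear",
        # STAT6 cycling: phospho-dependent part is always present
        "pS_c -> pS_n @ k_nuc_in",
        "S_n -> S_c @ k_nuc_out",
    ]
    if not topology.stat_cycling_phospho_dependent:
        # phospho-independent: both forms shuttle in both directions
        rxns += [
            "S_c -> S_n @ k_nuc_in",
            "pS_n -> pS_c @ k_nuc_out",
        ]
    if topology.ptp_oxidation:
        rxns += [
            "P_c + ROS -> Pox @ k_ptp_ox",
            "Pox -> P_c @ k_ptp_red",
        ]
    if topology.jak_oxidation:
        # oxidation of the receptor-JAK complex blocks its activation;
        # re-reduction restores the activatable pool
        rxns += [
            "R + ROS -> Rox @ k_jak_ox",
            "Rox -> R @ k_jak_red",
        ]
    if topology.ros_ptp_shuttling:
        rxns += [
            "ROS + P_n -> ROS + P_c @ k_shuttle_out",
            "P_c -> P_n @ k_shuttle_in",
        ]

    reactions = [parse_reaction(r) for r in rxns]
    used = {name for rxn in reactions for name, _ in rxn.reactants + rxn.products}
    species = [s for s in REDUCED_SPECIES_ORDER if s in used]
    params = dict(DEFAULT_REDUCED_PARAMETERS)
    if parameters:
        params.update(parameters)
    # drop constants of absent mechanisms so serialized models are minimal
    used_rates = {r.rate for r in reactions}
    params = {k: v for k, v in params.items() if k in used_rates}
    init = dict(DEFAULT_REDUCED_INITIAL_STATE)
    if initial_state is not None:
        init = dict(initial_state)
    init = {k: v for k, v in init.items() if k in set(species)}
    return ReactionSystem(
        species=species,
        reactions=reactions,
        parameters=params,
        initial_state=init,
        compartments={s: _COMPARTMENT[s] for s in species},
        name=topology.label,
    )
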
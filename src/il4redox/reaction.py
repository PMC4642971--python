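"""Mass-action reaction systems and their ODE right-hand sides.

A :class:`ReactionSystem` is an ordered list of named species, a list of
elementary mass-action reactions, a parameter map and an initial state.
Each reaction's flux is ``k * prod(reactant amounts)`` (with multiplicity),
optionally multiplied by time-dependent external inputs (e.g. a measured
ROS drive) listed as *modifiers*.  One non-mass-action rate law is
supported — a saturating (Michaelis-type) zeroth-order production term —
because induced protein synthesis saturates with transcription-factor
level and cannot be written as an elementary reaction.

Amounts are in arbitrary units, time in minutes, and compartments are
bookkeeping tags (equal effective volumes are assumed throughout).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import odeint

__all__ = [
    "Reaction",
    "SaturatingProduction",
    "ReactionSystem",
    "parse_reaction",
    "format_reaction",
]

_ARROW = re.compile(r"^\s*(.*?)\s*->\s*(.*?)\s*@\s*(\S+)\s*$")
_EMPTY = {"", "0", "∅", "phi", "Phi"}


def _parse_side(side: str) -> tuple[tuple[str, int], ...]:
    side = side.strip()
    if side in _EMPTY:
        return ()
    out: list[tuple[str, int]] = []
    for term in side.split("+"):
        term = term.strip()
        m = re.match(r"^(\d+)\s*\*?\s*(\S+)$", term)
        if m:
            out.append((m.group(2), int(m.group(1))))
        else:
            out.append((term, 1))
    return tuple(out)


def parse_reaction(text: str, modifiers: tuple[str, ...] = ()) -> "Reaction":
    """Parse ``"A + B -> C @ k1"`` (use ``0`` for an empty side)."""
    m = _ARROW.match(text)
    if m is None:
        raise ValueError(f"cannot parse reaction string: {text!r}")
    return Reaction(_parse_side(m.group(1)), _parse_side(m.group(2)), m.group(3),
                    modifiers=tuple(modifiers))


def _format_side(side: tuple[tuple[str, int], ...]) -> str:
    if not side:
        return "0"
    return " + ".join(name if n == 1 else f"{n} {name}" for name, n in side)


def format_reaction(rxn: "Reaction") -> str:
    s = f"{_format_side(rxn.reactants)} -> {_format_side(rxn.products)} @ {rxn.rate}"
    if rxn.modifiers:
        s += " * " + " * ".join(rxn.modifiers)
    return s


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants``/``products`` are ((species, stoichiometry), ...) tuples;
    ``rate`` names the rate constant; ``modifiers`` name external inputs
    whose instantaneous value multiplies the flux (they are not consumed).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: str
    modifiers: tuple[str, ...] = ()


@dataclass(frozen=True)
class SaturatingProduction:
    """Zeroth-order production saturating in a driver pool.

    rate = vmax * D / (km + D) with D the summed amount of ``drivers``.
    """

    product: str
    vmax: str
    km: str
    drivers: tuple[str, ...]


@dataclass
class ReactionSystem:
    species: list[str]
    reactions: list[Reaction]
    parameters: dict[str, float]
    initial_state: dict[str, float]
    compartments: dict[str, str] = field(default_factory=dict)
    constant_species: frozenset[str] = frozenset()
    inputs: dict[str, object] = field(default_factory=dict)  # name -> callable t -> value
    saturating: list[SaturatingProduction] = field(default_factory=list)
    name: str = ""

    # -- construction helpers -------------------------------------------------

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.species)}
        if len(idx) != len(self.species):
            raise ValueError("duplicate species names")
        self._index = idx
        for rxn in self.reactions:
            for name, _ in rxn.reactants + rxn.products:
                if name not in idx:
                    raise ValueError(f"reaction references unknown species {name!r}")
        for sp in self.saturating:
            if sp.product not in idx:
                raise ValueError(f"saturating production of unknown species {sp.product!r}")
        self._compiled = None

    @property
    def index(self) -> dict[str, int]:
        return dict(self._index)

    def y0(self) -> np.ndarray:
        y = np.zeros(len(self.species))
        for name, v in self.initial_state.items():
            y[self._index[name]] = v
        return y

    def with_parameters(self, **updates: float) -> "ReactionSystem":
        params = {**self.parameters, **updates}
        sys = replace(self, parameters=params)
        return sys

    # -- stoichiometry & fluxes -----------------------------------------------

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, species x reactions; constant species rows are zero."""
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name, n in rxn.reactants:
                N[self._index[name], j] -= n
            for name, n in rxn.products:
                N[self._index[name], j] += n
        for name in self.constant_species:
            N[self._index[name], :] = 0.0
        return N

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        N = self.stoichiometry_matrix()
        ridx: list[int] = []
        rptr = [0]
        kvec = np.empty(len(self.reactions))
        mod_idx: list[list[int]] = []
        input_names = sorted(self.inputs)
        input_pos = {n: i for i, n in enumerate(input_names)}
        for j, rxn in enumerate(self.reactions):
            for name, n in rxn.reactants:
                ridx.extend([self._index[name]] * n)
            rptr.append(len(ridx))
            kvec[j] = self.parameters[rxn.rate]
            mod_idx.append([input_pos[m] for m in rxn.modifiers])
        sat = [
            (self._index[sp.product], self.parameters[sp.vmax], self.parameters[sp.km],
             np.array([self._index[d] for d in sp.drivers], dtype=np.intp))
            for sp in self.saturating
        ]
        self._compiled = (
            N,
            np.array(ridx, dtype=np.intp),
            np.array(rptr, dtype=np.intp),
            kvec,
            mod_idx,
            [self.inputs[n] for n in input_names],
            sat,
        )
        return self._compiled

    def rate_vector(self, parameters: dict[str, float] | None = None) -> np.ndarray:
        p = self.parameters if parameters is None else parameters
        return np.array([p[rxn.rate] for rxn in self.reactions])

    def fluxes(self, t: float, y: np.ndarray,
               parameters: dict[str, float] | None = None) -> np.ndarray:
        """Per-reaction mass-action fluxes at state y (clipped at zero)."""
        N, ridx, rptr, kvec, mod_idx, input_fns, _ = self._compile()
        if parameters is not None:
            kvec = self.rate_vector(parameters)
        yc = np.maximum(y, 0.0)
        v = kvec.copy()
        for j in range(len(v)):
            for i in range(rptr[j], rptr[j + 1]):
                v[j] *= yc[ridx[i]]
            for m in mod_idx[j]:
                v[j] *= max(input_fns[m](t), 0.0)
        return v

    def rhs(self, t: float, y: np.ndarray,
            parameters: dict[str, float] | None = None) -> np.ndarray:
        N = self._compile()[0]
        dy = N @ self.fluxes(t, y, parameters)
        p = self.parameters if parameters is None else parameters
        yc = np.maximum(y, 0.0)
        for sp in self.saturating:
            d = sum(yc[self._index[s]] for s in sp.drivers)
            vmax, km = p[sp.vmax], p[sp.km]
            if sp.product not in self.constant_species:
                dy[self._index[sp.product]] += vmax * d / (km + d)
        return dy

    # -- simulation ------------------------------------------------------------

    def make_rhs(self, parameters: dict[str, float] | None = None):
        """Compiled-core RHS closure f(t, y) -> dy (used by the integrator)."""
        from ._fastsim import _mass_action_rhs

        N, ridx, rptr, kvec, mod_idx, input_fns, _ = self._compile()
        p = self.parameters if parameters is None else parameters
        kbase = self.rate_vector(p)
        mod_rxns = [(j, [input_fns[m] for m in mods])
                    for j, mods in enumerate(mod_idx) if mods]
        sat = [
            (self._index[sp.product], float(p[sp.vmax]), float(p[sp.km]),
             [self._index[d] for d in sp.drivers])
            for sp in self.saturating if sp.product not in self.constant_species
        ]
        ns = len(self.species)

        def rhs(t, y):
            k = kbase
            if mod_rxns:
                k = kbase.copy()
                for j, fns in mod_rxns:
                    for fn in fns:
                        k[j] *= max(float(fn(t)), 0.0)
            out = np.empty(ns)
            _mass_action_rhs(np.ascontiguousarray(y, dtype=float), k, ridx,
                             rptr, N, out)
            for pidx, vmax, km, didx in sat:
                d = sum(max(y[i], 0.0) for i in didx)
                out[pidx] += vmax * d / (km + d)
            return out

        return rhs

    def simulate(self, t_eval: np.ndarray, y0: np.ndarray | None = None,
                 parameters: dict[str, float] | None = None,
                 rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
        """Integrate with LSODA; returns array of shape (len(t_eval), n_species)."""
        t_eval = np.asarray(t_eval, dtype=float)
        if y0 is None:
            y0 = self.y0()
        sol, info = odeint(self.make_rhs(parameters), np.asarray(y0, dtype=float),
                           t_eval, tfirst=True, rtol=rtol, atol=atol,
                           mxstep=50000, full_output=True)
        if info["message"] != "Integration successful.":
            raise RuntimeError(f"ODE integration failed: {info['message']}")
        return sol

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "compartments": dict(self.compartments),
            "constant_species": sorted(self.constant_species),
            "reactions": [format_reaction(r) for r in self.reactions],
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "initial_state": {k: float(v) for k, v in self.initial_state.items()},
            "saturating": [
                {"product": s.product, "vmax": s.vmax, "km": s.km,
                 "drivers": list(s.drivers)}
                for s in self.saturating
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, inputs: dict | None = None) -> "ReactionSystem":
        reactions = []
        for text in d["reactions"]:
            mods: tuple[str, ...] = ()
            if " * " in text:
                text, mod_part = text.split(" * ", 1)
                mods = tuple(m.strip() for m in mod_part.split("*"))
            reactions.append(parse_reaction(text, mods))
        return cls(
            species=list(d["species"]),
            reactions=reactions,
            parameters=dict(d["parameters"]),
            initial_state=dict(d["initial_state"]),
            compartments=dict(d.get("compartments", {})),
            constant_species=frozenset(d.get("constant_species", ())),
            inputs=dict(inputs or {}),
            saturating=[
                SaturatingProduction(s["product"], s["vmax"], s["km"], tuple(s["drivers"]))
                for s in d.get("saturating", ())
            ],
            name=d.get("name", ""),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str, inputs: dict | None = None) -> "ReactionSystem":
        return cls.from_dict(yaml.safe_load(text), inputs=inputs)
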
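import numpy as np
import pytest

from il4redox.network_library import enumerate_topologies


@pytest.fixture(scope="session")
def topologies():
    return {t.label: t for t in enumerate_topologies()}


@pytest.fixture(scope="session")
def time_grid():
    return np.arange(0.0, 120.5, 0.5)


def brute_force_rhs(system, t, y, parameters=None):
    """Independent mass-action oracle: stoichiometry matrix times fluxes.

    Works directly from the reaction multisets, without touching the
    compiled representation the implementation integrates.
    """
    p = system.parameters if parameters is None else parameters
    idx = {s: i for i, s in enumerate(system.species)}
    dy = np.zeros(len(system.species))
    yc = np.maximum(np.asarray(y, float), 0.0)
    for rxn in system.reactions:
        flux = p[rxn.rate]
        for name, n in rxn.reactants:
            flux *= yc[idx[name]] ** n
        for m in rxn.modifiers:
            flux *= max(float(system.inputs[m](t)), 0.0)
        for name, n in rxn.reactants:
            if name not in system.constant_species:
                dy[idx[name]] -= n * flux
        for name, n in rxn.products:
            if name not in system.constant_species:
                dy[idx[name]] += n * flux
    for sp in system.saturating:
        d = sum(yc[idx[s]] for s in sp.drivers)
        if sp.product not in system.constant_species:
            dy[idx[sp.product]] += p[sp.vmax] * d / (p[sp.km] + d)
    return dy
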
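"""Shared fixtures: small synthetic systems and coarse, fast grids."""

from __future__ import annotations

import numpy as np
import pytest

import cupredox as cx
from cupredox.forcefield import OXIDIZED, REDUCED, parameterize


@pytest.fixture(scope="session")
def toy_site():
    """Toy copper site structure plus its two-state charge set."""
    return cx.make_fixture("toy_copper_site")


@pytest.fixture(scope="session")
def toy_site_states(toy_site):
    """Parameterized OX/RED pair of the toy copper site."""
    structure, cuset = toy_site
    prot = cx.assign_protonation(structure)
    ox = parameterize(prot, cu_set=cuset, oxidation_state=OXIDIZED)
    red = parameterize(prot, cu_set=cuset, oxidation_state=REDUCED)
    return ox, red


@pytest.fixture(scope="session")
def toy_grid():
    """Coarse grid enclosing the toy site, centered near its centroid."""
    return cx.GridSpec((2.0, -0.5, -2.8), 26.0, 0.4)


@pytest.fixture(scope="session")
def mini_protein():
    return cx.make_fixture("mini_protein", {"sequence": "ADKLS"})


@pytest.fixture(scope="session")
def born_ion_ps():
    def make(q=1.0, radius=2.0, center=(0.0, 0.0, 0.0)):
        s = cx.make_fixture("born_ion", {"q": q, "radius": radius, "center": center})
        return cx.as_parameterized(s)

    return make


@pytest.fixture(scope="session")
def no_salt():
    return cx.SolverOptions(ionic_strength=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
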
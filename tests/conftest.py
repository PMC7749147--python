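"""Shared fixtures: pinned small reference tables and cached structures.

Tests pin explicit random-coil and weight tables wherever hand-computed
numbers are asserted, so results do not depend on the shipped defaults.
"""

import numpy as np
import pytest

from shiftflex.fixtures import FixtureSpec, make_structure
from shiftflex.network import build_graph
from shiftflex.rci import RandomCoilTable, WeightTable


@pytest.fixture(scope="session")
def pinned_rc() -> RandomCoilTable:
    """Tiny hand-checkable random-coil table (flat values, one correction)."""
    shifts = {
        "ALA": {"CA": 50.0, "CB": 20.0, "C": 175.0, "N": 120.0,
                "H": 8.0, "HA": 4.0},
        "GLY": {"CA": 45.0, "C": 174.0, "N": 109.0, "H": 8.3, "HA": 3.9},
        "PRO": {"CA": 63.0, "CB": 32.0, "C": 177.0, "N": 137.0, "HA": 4.4},
    }
    neighbor = {1: {"PRO": {"CA": -0.3}}}
    return RandomCoilTable(shifts=shifts, neighbor=neighbor,
                           provenance="pinned-test-table")


@pytest.fixture(scope="session")
def uniform_weights() -> WeightTable:
    return WeightTable(base={n: 1.0 for n in ("CA", "CB", "C", "N", "H", "HA")},
                       provenance="uniform-test-weights")


@pytest.fixture(scope="session")
def helix20():
    return make_structure(FixtureSpec("helix", length=20))


@pytest.fixture(scope="session")
def helix20_graph(helix20):
    return build_graph(helix20)


@pytest.fixture(scope="session")
def hairpin16():
    return make_structure(FixtureSpec("hairpin", length=16))
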
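"""Constraint network: covalent bars, hydrogen bonds, hydrophobic tethers."""

import math

import numpy as np
import pytest

from shiftflex.fixtures import FixtureSpec, make_structure
from shiftflex.network import (Bar, build_graph, covalent_bars, detect_hbonds,
                               detect_hydrophobics, hbond_energy)
from shiftflex.structure import AtomSite, Model


def _residue(restype, resnum, atoms):
    return [AtomSite(name, el, "A", resnum, "", restype, pos)
            for name, el, pos in atoms]


class TestCovalentBars:
    def test_single_and_double_bond_multiplicities(self):
        atoms = _residue("ALA", 1, [
            ("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
            ("C", "C", (2.0, 1.4, 0.0)), ("O", "O", (1.3, 2.4, 0.0)),
            ("CB", "C", (2.0, -0.8, 1.2))])
        bars = covalent_bars(Model(0, atoms))
        by_pair = {(b.i, b.j): b for b in bars}
        names = [a.name for a in atoms]
        n_ca = by_pair[tuple(sorted((names.index("N"), names.index("CA"))))]
        c_o = by_pair[tuple(sorted((names.index("C"), names.index("O"))))]
        assert n_ca.multiplicity == 5 and n_ca.kind == "single-covalent"
        assert c_o.multiplicity == 6 and c_o.kind == "double-covalent"
        assert len(bars) == 4  # N-CA, CA-C, C=O, CA-CB

    def test_peptide_bond_is_locked(self, helix20):
        bars = covalent_bars(helix20)
        c1 = helix20.atom_index(("A", 1, ""), "C")
        n2 = helix20.atom_index(("A", 2, ""), "N")
        pep = [b for b in bars if {b.i, b.j} == {c1, n2}]
        assert len(pep) == 1 and pep[0].multiplicity == 6

    def test_phe_ring_bonds_all_locked(self):
        # regular hexagon of ring atoms, 1.39 A sides
        ring = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = _residue("PHE", 1, [
            ("N", "N", (0.0, 0.0, -3.0)), ("CA", "C", (1.46, 0.0, -3.0)),
            ("C", "C", (2.0, 1.4, -3.0)), ("O", "O", (1.3, 2.4, -3.0)),
            ("CB", "C", (1.9, -0.9, -1.7))] + [
            (nm, "C", (1.39 * math.cos(k * math.pi / 3),
                       1.39 * math.sin(k * math.pi / 3), 0.0))
            for k, nm in enumerate(ring)])
        bars = covalent_bars(Model(0, atoms))
        ring_bars = [b for b in bars if b.kind == "double-covalent"
                     and b.multiplicity == 6]
        # C=O plus the six aromatic ring bonds
        assert len(ring_bars) == 7


class TestHbondEnergy:
    def _ideal(self, d=2.8, hybrid="sp2"):
        donor = np.array([0.0, 0.0, 0.0])
        h = np.array([0.0, 0.0, 1.0])
        acc = np.array([0.0, 0.0, d])
        phi0 = math.radians(120.0 if hybrid == "sp2" else 109.5)
        base = acc + np.array([math.sin(phi0), 0.0, -math.cos(phi0)])
        return donor, h, acc, base

    def test_ideal_geometry_gives_minus_v0(self):
        d, h, a, b = self._ideal()
        assert hbond_energy(d, h, a, b, "sp2") == pytest.approx(-8.0)
        d, h, a, b = self._ideal(hybrid="sp3")
        assert hbond_energy(d, h, a, b, "sp3") == pytest.approx(-8.0)

    def test_energy_vanishes_at_large_distance(self):
        d, h, a, b = self._ideal(d=40.0)
        e = hbond_energy(d, h, a, b, "sp2")
        assert -1e-6 < e <= 0.0

    def test_linear_in_angular_factor(self):
        # phi off-ideal by 45 deg -> angular factor cos^2(45) = 0.5
        donor, h, acc, _ = self._ideal()
        phi = math.radians(120.0 + 45.0)
        base = acc + np.array([math.sin(phi), 0.0, -math.cos(phi)])
        assert hbond_energy(donor, h, acc, base, "sp2") == pytest.approx(-4.0)

    def test_bent_geometry_rejected(self):
        donor = np.array([0.0, 0.0, 0.0])
        h = np.array([0.0, 0.0, 1.0])
        acc = np.array([0.0, 2.6, 1.0])  # ~90 deg at H
        assert hbond_energy(donor, h, acc) == 0.0


class TestDetectHbonds:
    def test_helix_has_i_to_i_plus_4_ladder(self, helix20):
        bars = detect_hbonds(helix20)
        pairs = set()
        for b in bars:
            ai, aj = helix20.atoms[b.i], helix20.atoms[b.j]
            if ai.name == "O" and aj.name == "H":
                pairs.add((ai.residue_number, aj.residue_number))
        for i in range(1, 17):
            assert (i, i + 4) in pairs

    def test_weak_pairs_excluded_by_cutoff(self, helix20):
        strict = detect_hbonds(helix20, include_cutoff=-1.0)
        default = detect_hbonds(helix20, include_cutoff=-0.01)
        assert len(strict) < len(default)
        assert all(b.energy_kcal <= -1.0 for b in strict)

    def test_carbon_is_never_a_donor(self, helix20):
        bars = detect_hbonds(helix20)
        for b in bars:
            heavy = [a for a in (helix20.atoms[b.i], helix20.atoms[b.j])
                     if a.element != "H"]
            assert all(a.element in ("N", "O", "S") for a in heavy)


class TestDetectHydrophobics:
    def _methane_pair(self, gap):
        atoms = [AtomSite("CB", "C", "A", 1, "", "ALA", (0.0, 0.0, 0.0)),
                 AtomSite("CB", "C", "A", 9, "", "ALA", (gap, 0.0, 0.0))]
        return Model(0, atoms)

    def test_contact_pair_gets_two_bars(self):
        bars = detect_hydrophobics(self._methane_pair(3.5), topology=[])
        assert len(bars) == 1
        assert bars[0].multiplicity == 2 and bars[0].kind == "hydrophobic"

    def test_pair_beyond_threshold_excluded(self):
        # threshold = 1.7 + 1.7 + 0.25 = 3.65
        assert detect_hydrophobics(self._methane_pair(4.15), topology=[]) == []

    def test_topologically_close_pair_excluded(self):
        model = self._methane_pair(3.0)
        # 2 covalent bonds apart via a bridging atom index 1? use direct
        # topology: 0-1 bonded through a virtual intermediate is impossible
        # with two atoms, so bond them directly (1 bond apart)
        bars = detect_hydrophobics(model, topology=[(0, 1, 1)])
        assert bars == []

    def test_polar_neighbour_disqualifies(self):
        atoms = [AtomSite("CB", "C", "A", 1, "", "SER", (0.0, 0.0, 0.0)),
                 AtomSite("OG", "O", "A", 1, "", "SER", (1.4, 0.0, 0.0)),
                 AtomSite("CB", "C", "A", 9, "", "ALA", (0.0, 3.4, 0.0))]
        bars = detect_hydrophobics(Model(0, atoms), topology=[(0, 1, 1)])
        assert bars == []


class TestBuildGraph:
    def test_vertex_count_and_composition(self, helix20, helix20_graph):
        g = helix20_graph
        assert g.n_vertices == len(helix20.atoms)
        kinds = {b.kind for b in g.bars}
        assert "single-covalent" in kinds and "hbond" in kinds
        assert all(b.multiplicity in (2, 5, 6) for b in g.bars)
        assert all(b.i != b.j for b in g.bars)

    def test_hbond_bars_sorted_weakest_first(self, helix20_graph):
        energies = [b.energy_kcal for b in helix20_graph.hbond_bars]
        assert energies == sorted(energies, reverse=True)
        assert all(e <= -0.01 for e in energies)

    def test_deterministic_rebuild(self, helix20):
        g1 = build_graph(helix20)
        g2 = build_graph(helix20)
        assert [(b.i, b.j, b.multiplicity, b.kind, b.energy_kcal)
                for b in g1.bars] == \
               [(b.i, b.j, b.multiplicity, b.kind, b.energy_kcal)
                for b in g2.bars]

    def test_bar_invariants_enforced(self):
        with pytest.raises(ValueError):
            Bar(0, 0, 5, "single-covalent")
        with pytest.raises(ValueError):
            Bar(0, 1, 4, "single-covalent")
        with pytest.raises(ValueError):
            Bar(0, 1, 5, "hbond", energy_kcal=None)
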
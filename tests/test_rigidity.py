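"""Pebble game, rigid clusters, dilution and Boltzmann conversion.

Small hand-checkable cases are asserted directly; random multigraphs are
cross-checked against the brute-force rank oracle (exhaustive sparsity
counting + randomized rigidity-matrix rank over a prime field).
"""

import numpy as np
import pytest

from shiftflex.fixtures import SimpleGraph, oracle_dof, random_multigraph
from shiftflex.network import Bar, ConstraintGraph
from shiftflex.rigidity import (GAS_CONSTANT, DilutionResult, Sentinel,
                                boltzmann_flex, dilution, pebble_game,
                                residue_rigidity, rigid_clusters)


def _graph(n, edges):
    return SimpleGraph.from_edges(n, edges)


class TestPebbleGame:
    def test_isolated_vertex_has_six_dof(self):
        state = pebble_game(_graph(1, []))
        assert state.dof == 6

    def test_single_bond_removes_five_dof(self):
        state = pebble_game(_graph(2, [(0, 1, 5)]))
        assert state.dof == 7

    def test_seven_parallel_bars_one_redundant(self):
        state = pebble_game(_graph(2, [(0, 1, 7)]))
        assert state.dof == 6
        assert state.game.independent == 6
        assert state.game.redundant == 1

    def test_insertion_order_does_not_change_dof_or_clusters(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g = random_multigraph(rng, max_vertices=7, max_bars=30)
            edges = [(b.i, b.j, b.multiplicity) for b in g.bars]
            perm = rng.permutation(len(edges))
            g2 = SimpleGraph.from_edges(g.n_vertices,
                                        [edges[k] for k in perm])
            s1, s2 = pebble_game(g), pebble_game(g2)
            assert s1.dof == s2.dof
            d1 = rigid_clusters(s1, g)
            d2 = rigid_clusters(s2, g2)
            assert d1.as_sets() == d2.as_sets()

    def test_adding_bars_never_increases_dof(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_multigraph(rng, max_vertices=6, max_bars=25)
            edges = [(b.i, b.j, b.multiplicity) for b in g.bars]
            dofs = []
            for k in range(len(edges) + 1):
                dofs.append(pebble_game(
                    SimpleGraph.from_edges(g.n_vertices, edges[:k])).dof)
            assert all(a >= b for a, b in zip(dofs, dofs[1:]))


class TestRigidClusters:
    def test_six_bars_fuse_two_bodies(self):
        g = _graph(2, [(0, 1, 6)])
        decomp = rigid_clusters(pebble_game(g), g)
        assert decomp.as_sets() == {frozenset({0, 1})}

    def test_five_bars_leave_singletons(self):
        g = _graph(2, [(0, 1, 5)])
        decomp = rigid_clusters(pebble_game(g), g)
        assert decomp.as_sets() == {frozenset({0}), frozenset({1})}

    def test_triangle_of_five_bar_bonds_is_rigid(self):
        g = _graph(3, [(0, 1, 5), (1, 2, 5), (0, 2, 5)])
        decomp = rigid_clusters(pebble_game(g), g)
        assert decomp.as_sets() == {frozenset({0, 1, 2})}

    def test_cluster_ids_are_lowest_member(self):
        g = _graph(4, [(2, 3, 6)])
        decomp = rigid_clusters(pebble_game(g), g)
        assert decomp.cluster_of(3) == 2
        assert decomp.cluster_of(0) == 0


class TestOracleEquivalence:
    def test_pebble_game_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(150):
            g = random_multigraph(rng, max_vertices=8, max_bars=30)
            state = pebble_game(g)
            decomp = rigid_clusters(state, g)
            dof, clusters = oracle_dof(g, rng)
            assert state.dof == dof
            assert decomp.as_sets() == clusters


def _chain_graph(n_atoms, bond_mult=6, extra=()):
    """Path of bodies with locked bonds (one rigid block) + extra bars,
    each atom its own residue, atom k is residue k's CA."""
    bars = [Bar(k, k + 1, bond_mult,
                "double-covalent" if bond_mult == 6 else "single-covalent")
            for k in range(n_atoms - 1)]
    bars += list(extra)
    return ConstraintGraph(
        n_vertices=n_atoms, bars=bars,
        atom_residue=list(range(n_atoms)),
        residue_ids=[("A", k + 1, "") for k in range(n_atoms)],
        ca_atoms={k: k for k in range(n_atoms)})


class TestResidueRigidity:
    def test_fifteen_atom_threshold_boundary(self):
        for n, expect in ((14, False), (15, True)):
            g = _chain_graph(n)
            decomp = rigid_clusters(pebble_game(g), g)
            rigid = residue_rigidity(decomp, g)
            assert bool(rigid[0]) is expect

    def test_small_rigid_ring_not_counted(self):
        # a proline-like rigid unit smaller than 15 atoms stays flexible
        g = _chain_graph(5)
        rigid = residue_rigidity(rigid_clusters(pebble_game(g), g), g)
        assert not rigid.any()

    def test_threshold_is_configurable(self):
        g = _chain_graph(5)
        rigid = residue_rigidity(rigid_clusters(pebble_game(g), g), g,
                                 min_atoms=3)
        assert rigid.all()


class TestDilution:
    def _two_block_graph(self, hb_energy=-2.0):
        """Two 8-atom rigid blocks joined by a single bond plus one
        hydrogen bond: rigid together only while the hbond is present."""
        bars = [Bar(k, k + 1, 6, "double-covalent") for k in range(7)]
        bars += [Bar(8 + k, 9 + k, 6, "double-covalent") for k in range(7)]
        bars += [Bar(7, 8, 5, "single-covalent"),
                 Bar(0, 15, 5, "hbond", energy_kcal=hb_energy)]
        return ConstraintGraph(
            n_vertices=16, bars=bars,
            atom_residue=list(range(16)),
            residue_ids=[("A", k + 1, "") for k in range(16)],
            ca_atoms={k: k for k in range(16)})

    def test_two_state_transition_energy(self):
        g = self._two_block_graph(hb_energy=-2.0)
        result = dilution(g, include_cutoff=-0.01, min_atoms=15)
        assert all(e == -2.0 for e in result.energies)

    def test_terminal_residue_always_flexible(self, helix20_graph):
        result = dilution(helix20_graph)
        assert result.energies[-1] is Sentinel.ALWAYS_FLEXIBLE

    def test_never_flexible_when_covalently_rigid(self):
        g = _chain_graph(16, extra=[Bar(0, 15, 5, "hbond", energy_kcal=-1.0)])
        result = dilution(g, include_cutoff=-0.01, min_atoms=15)
        assert all(e is Sentinel.NEVER_FLEXIBLE for e in result.energies)

    def test_monotone_rigidity_trace(self, helix20_graph, hairpin16):
        from shiftflex.network import build_graph
        for graph in (helix20_graph, build_graph(hairpin16)):
            trace = dilution(graph).rigidity_trace
            # once flexible at a cutoff, flexible at all stronger cutoffs
            assert not np.any(~trace[:-1] & trace[1:])


class TestBoltzmann:
    def test_zero_energy_gives_probability_one(self):
        res = DilutionResult(energies=[0.0], schedule=[0.0],
                             residue_ids=[("A", 1, "")])
        assert boltzmann_flex(res).values[0] == pytest.approx(1.0)

    def test_sentinels_map_to_extremes(self):
        res = DilutionResult(
            energies=[Sentinel.ALWAYS_FLEXIBLE, Sentinel.NEVER_FLEXIBLE],
            schedule=[0.0], residue_ids=[("A", 1, ""), ("A", 2, "")])
        vals = boltzmann_flex(res).values
        assert vals[0] == 1.0 and vals[1] == 0.0

    def test_half_probability_at_rt_ln2(self):
        e = -GAS_CONSTANT * 298.15 * np.log(2.0)
        res = DilutionResult(energies=[e], schedule=[0.0],
                             residue_ids=[("A", 1, "")])
        assert boltzmann_flex(res).values[0] == pytest.approx(0.5, abs=1e-12)


class TestHelixFixtureRigidity:
    def test_interior_rigid_termini_flexible_at_full_network(self, helix20_graph):
        state = pebble_game(helix20_graph)
        decomp = rigid_clusters(state, helix20_graph)
        rigid = residue_rigidity(decomp, helix20_graph)
        assert rigid[4:16].all()
        assert not rigid[-1] or not rigid[0]
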
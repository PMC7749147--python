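"""Body-bar rigidity: (6,6) pebble game, rigid clusters, hydrogen-bond
dilution and conversion of transition energies to flexibility probabilities.

Each atom-body starts with six pebbles (degrees of freedom).  A bar is
independent iff seven pebbles can be gathered on its two endpoints, the
combinatorial expression of (6,6)-sparsity: every sub-multigraph satisfies
|E'| <= 6|V'| - 6.  By Tay's theorem this matroid coincides with generic
body-bar rigidity, so the pebble game computes exact degrees of freedom and
rigid clusters.  Two bodies are mutually rigid iff a further generic bar
between them would be redundant, i.e. seven pebbles cannot be gathered on
the pair; mutual rigidity is an equivalence relation on bodies and its
classes are the rigid clusters.

Hydrogen-bond dilution removes hydrogen bonds weakest to strongest
(distinct energies, ties removed together), repeating the decomposition at
each cutoff and recording the first cutoff at which each residue's CA atom
stops belonging to a rigid cluster of at least 15 atoms.  The transition
energy E_c maps to a flexibility probability via the Boltzmann factor
p = exp(E_c / RT) at 298.15 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .network import ConstraintGraph
from .rci import FlexibilityProfile

GAS_CONSTANT = 0.0019872     # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K
RIGID_CLUSTER_MIN_ATOMS = 15
PEBBLES_PER_BODY = 6


class Sentinel(Enum):
    ALWAYS_FLEXIBLE = "always_flexible"
    NEVER_FLEXIBLE = "never_flexible"


class PebbleGame:
    """(6,6) body-bar pebble game on a multigraph of bodies.

    Bars are inserted greedily in the order given; searches are depth-first
    with lowest-vertex-first tie-breaking, so the directed pebble structure
    (though not the matroid outcome) is deterministic.
    """

    def __init__(self, n_vertices: int):
        self.n = n_vertices
        self.free = [PEBBLES_PER_BODY] * n_vertices
        # out[u][v] = number of directed edges u -> v (pebbles of u on bars)
        self.out: list[dict[int, int]] = [dict() for _ in range(n_vertices)]
        self.independent = 0
        self.redundant = 0

    # -- pebble search -----------------------------------------------------
    def _find_pebble(self, start: int, forbidden: tuple[int, int]) -> bool:
        """DFS for a free pebble reachable from ``start``; on success the
        path is reversed, moving one pebble onto ``start``."""
        parent = {start: None}
        stack = [start]
        target = -1
        while stack:
            u = stack.pop()
            for v in sorted(self.out[u]):
                if v in parent:
                    continue
                parent[v] = u
                if self.free[v] > 0 and v != forbidden[0] and v != forbidden[1]:
                    target = v
                    stack.clear()
                    break
                stack.append(v)
        if target < 0:
            return False
        self.free[target] -= 1
        v = target
        while parent[v] is not None:
            u = parent[v]
            # reverse one edge u -> v
            self.out[u][v] -= 1
            if self.out[u][v] == 0:
                del self.out[u][v]
            self.out[v][u] = self.out[v].get(u, 0) + 1
            v = u
        self.free[start] += 1
        return True

    def _gather(self, u: int, v: int, needed: int = 7) -> bool:
        """Try to gather ``needed`` free pebbles on the pair (u, v)."""
        while self.free[u] + self.free[v] < needed:
            if self.free[u] < PEBBLES_PER_BODY and self._find_pebble(u, (u, v)):
                continue
            if self.free[v] < PEBBLES_PER_BODY and self._find_pebble(v, (u, v)):
                continue
            return False
        return True

    # -- public operations -------------------------------------------------
    def insert_bar(self, u: int, v: int) -> bool:
        """Insert one bar; returns True if independent."""
        if u == v:
            raise ValueError("self-edges are not allowed")
        if not self._gather(u, v):
            self.redundant += 1
            return False
        payer = u if self.free[u] > 0 else v
        other = v if payer == u else u
        self.free[payer] -= 1
        self.out[payer][other] = self.out[payer].get(other, 0) + 1
        self.independent += 1
        return True

    def pair_is_rigid(self, u: int, v: int) -> bool:
        """True iff a further generic bar u-v would be redundant."""
        return not self._gather(u, v)

    @property
    def dof(self) -> int:
        """Total remaining degrees of freedom (including the 6 global)."""
        return sum(self.free)


@dataclass
class PebbleState:
    """Result of playing the pebble game over a bar list."""

    game: PebbleGame
    bar_independent: list[int]   # independent bar count per input Bar
    n_bars: int

    @property
    def dof(self) -> int:
        return self.game.dof


@dataclass
class RigidClusterDecomposition:
    """Partition of atoms into maximal rigid clusters."""

    labels: np.ndarray            # cluster id per vertex (lowest member id)
    cutoff: float | None = None   # hbond cutoff at which computed

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def cluster_of(self, vertex: int) -> int:
        return int(self.labels[vertex])

    def as_sets(self) -> set[frozenset]:
        out: dict[int, set] = {}
        for v, c in enumerate(self.labels):
            out.setdefault(int(c), set()).add(v)
        return {frozenset(s) for s in out.values()}


def _bar_list(graph) -> tuple[int, list[tuple[int, int, int]]]:
    """(n_vertices, [(u, v, multiplicity)]) from a ConstraintGraph or any
    object exposing ``n_vertices`` and ``bars`` with i/j/multiplicity."""
    bars = [(b.i, b.j, b.multiplicity) for b in graph.bars]
    return graph.n_vertices, bars


def pebble_game(graph, bars=None) -> PebbleState:
    """Play the (6,6) pebble game over the graph's bars (deterministic order)."""
    n, default_bars = _bar_list(graph)
    if bars is not None:
        default_bars = [(b.i, b.j, b.multiplicity) for b in bars]
    game = PebbleGame(n)
    per_bar = []
    total = 0
    for u, v, mult in default_bars:
        indep = 0
        for _ in range(mult):
            if game.insert_bar(u, v):
                indep += 1
        per_bar.append(indep)
        total += mult
    return PebbleState(game=game, bar_independent=per_bar, n_bars=total)


def rigid_clusters(state: PebbleState, graph, bars=None,
                   cutoff: float | None = None) -> RigidClusterDecomposition:
    """Maximal rigid clusters via pairwise redundancy tests + union-find."""
    n, bar_list = _bar_list(graph)
    if bars is not None:
        bar_list = [(b.i, b.j, b.multiplicity) for b in bars]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = sorted({(min(u, v), max(u, v)) for u, v, _ in bar_list})
    for u, v in pairs:
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        if state.game.pair_is_rigid(u, v):
            parent[max(ru, rv)] = min(ru, rv)
    # label clusters by their lowest member id
    roots: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for v in range(n):
        r = find(v)
        if r not in roots:
            roots[r] = v  # first (lowest) vertex seen with this root
        out[v] = roots[r]
    return RigidClusterDecomposition(labels=out, cutoff=cutoff)


def residue_rigidity(decomp: RigidClusterDecomposition, graph: ConstraintGraph,
                     min_atoms: int = RIGID_CLUSTER_MIN_ATOMS) -> np.ndarray:
    """Per-residue boolean: rigid iff CA's cluster holds >= ``min_atoms``.

    The size threshold stops small covalently rigid units (proline and
    aromatic rings) from counting as rigid on their own.  Residues lacking
    a CA atom are flexible.
    """
    sizes = decomp.cluster_sizes()
    n_res = len(graph.residue_ids)
    out = np.zeros(n_res, dtype=bool)
    for k in range(n_res):
        ca = graph.ca_atoms.get(k)
        if ca is None:
            continue
        out[k] = sizes[decomp.cluster_of(ca)] >= min_atoms
    return out


@dataclass
class DilutionResult:
    """Per-residue hydrogen-bond transition energies.

    ``energies[k]`` is the first (least negative) cutoff at which residue k
    is no longer rigid, or a :class:`Sentinel`: ALWAYS_FLEXIBLE for residues
    never rigid even with every hydrogen bond present, NEVER_FLEXIBLE for
    residues still rigid with zero hydrogen bonds.
    """

    energies: list[float | Sentinel]
    schedule: list[float]
    residue_ids: list[tuple[str, int, str]]
    rigidity_trace: np.ndarray = None  # (n_steps+1, n_res) bool, incl. 0-hbond step


def dilution(graph: ConstraintGraph, include_cutoff: float | None = None,
             min_atoms: int = RIGID_CLUSTER_MIN_ATOMS) -> DilutionResult:
    """Hydrogen-bond dilution: sweep cutoffs weakest to strongest.

    The schedule starts at ``include_cutoff`` (every retained bond present)
    and then visits each distinct hydrogen-bond energy in descending order;
    at cutoff c every bond with energy > c is absent.  A final decomposition
    with zero hydrogen bonds identifies NEVER_FLEXIBLE residues; residues
    that first become flexible only there are assigned the strongest bond
    energy.  The decomposition is recomputed from scratch at each step.
    """
    hbonds = graph.hbond_bars
    energies = sorted({b.energy_kcal for b in hbonds}, reverse=True)
    if include_cutoff is None:
        include_cutoff = energies[0] if energies else 0.0
    schedule = [include_cutoff] + [e for e in energies if e < include_cutoff]
    n_res = len(graph.residue_ids)
    first_flexible: list[float | None] = [None] * n_res
    trace = []
    for cutoff in schedule + [None]:
        bars = graph.bars_at_cutoff(cutoff)
        state = pebble_game(graph, bars=bars)
        decomp = rigid_clusters(state, graph, bars=bars, cutoff=cutoff)
        rigid = residue_rigidity(decomp, graph, min_atoms=min_atoms)
        trace.append(rigid)
        for k in range(n_res):
            if not rigid[k] and first_flexible[k] is None:
                # the zero-hbond step carries the strongest bond energy
                first_flexible[k] = cutoff if cutoff is not None else \
                    (schedule[-1] if energies else include_cutoff)
    result: list[float | Sentinel] = []
    for k in range(n_res):
        if first_flexible[k] is None:
            result.append(Sentinel.NEVER_FLEXIBLE)
        elif first_flexible[k] == schedule[0]:
            result.append(Sentinel.ALWAYS_FLEXIBLE)
        else:
            result.append(first_flexible[k])
    return DilutionResult(energies=result, schedule=schedule,
                          residue_ids=graph.residue_ids,
                          rigidity_trace=np.array(trace))


def boltzmann_flex(result: DilutionResult,
                   temperature: float = DEFAULT_TEMPERATURE) -> FlexibilityProfile:
    """Convert transition energies to flexibility probabilities.

    p = exp(E_c / RT), clamped to [0, 1]; ALWAYS_FLEXIBLE -> 1,
    NEVER_FLEXIBLE -> 0.
    """
    rt = GAS_CONSTANT * temperature
    values = np.empty(len(result.energies))
    for k, e in enumerate(result.energies):
        if e is Sentinel.ALWAYS_FLEXIBLE:
            values[k] = 1.0
        elif e is Sentinel.NEVER_FLEXIBLE:
            values[k] = 0.0
        else:
            values[k] = min(1.0, max(0.0, float(np.exp(e / rt))))
    resnums = np.array([rid[1] for rid in result.residue_ids])
    chain = result.residue_ids[0][0] if result.residue_ids else "A"
    return FlexibilityProfile(resnums, values,
                              np.ones(len(values), dtype=bool),
                              source="RIGIDITY", chain=chain)


def rigidity_profile(graph: ConstraintGraph,
                     temperature: float = DEFAULT_TEMPERATURE,
                     min_atoms: int = RIGID_CLUSTER_MIN_ATOMS,
                     include_cutoff: float | None = None) -> FlexibilityProfile:
    """Convenience: dilution followed by Boltzmann conversion."""
    return boltzmann_flex(dilution(graph, include_cutoff=include_cutoff,
                                   min_atoms=min_atoms),
                          temperature=temperature)


def cluster_dump(graph: ConstraintGraph, cutoffs=None) -> "pandas.DataFrame":
    """Per-cutoff rigid-cluster table (cutoff, atom, cluster id, size)."""
    import pandas as pd

    if cutoffs is None:
        hb = graph.hbond_bars
        cutoffs = [hb[0].energy_kcal if hb else 0.0]
    rows = []
    for cutoff in cutoffs:
        bars = graph.bars_at_cutoff(cutoff)
        state = pebble_game(graph, bars=bars)
        decomp = rigid_clusters(state, graph, bars=bars, cutoff=cutoff)
        sizes = decomp.cluster_sizes()
        for v in range(graph.n_vertices):
            c = decomp.cluster_of(v)
            rows.append((cutoff, v, c, sizes[c]))
    return pd.DataFrame(rows, columns=["cutoff", "atom", "cluster", "size"])
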
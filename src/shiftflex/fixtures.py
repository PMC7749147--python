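"""Synthetic structures, shift tables and small graphs for testing.

Everything here is generated programmatically and seed-deterministic:
ideal poly-alanine secondary-structure fixtures built from standard
internal coordinates, shift tables constructed to invert the RCI pipeline
for a chosen target flexibility, and a brute-force rigidity oracle for
small body-bar multigraphs that double-checks the pebble game.

The oracle computes the generic body-bar rank two independent ways that
must agree: exhaustive (6,6)-sparsity counting over all vertex subsets,
and the rank of a randomized rigidity matrix whose bar rows carry Pluecker
line coordinates, evaluated over a large prime field so that rank needs no
floating-point tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rci import RCI_CAP, RCI_MODE, RandomCoilTable, WeightTable, smooth3
from .shifts import BACKBONE_NUCLEI, ShiftRecord, ShiftTable
from .structure import AtomSite, Model, ensure_protons

# backbone internal coordinates (Angstrom / degrees)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
      "CA-CB": 1.521}
_A = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
      "CA-C-O": 120.8, "N-CA-CB": 110.4}

TORSIONS = {
    "helix": (-57.0, -47.0),
    # hairpin strand/turn torsions tuned numerically so that the ideal
    # poly-Ala hairpin actually forms its cross-strand hydrogen-bond ladder
    # (rigid ideal-geometry strands cannot relax, so textbook beta torsions
    # leave the ladder open)
    "strand": (-88.0, 86.6),
    "turn": ((58.4, -48.4), (-145.7, -16.7)),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure/shift fixture."""

    kind: str            # helix | hairpin | coil | two-domain
    length: int = 20
    seed: int = 0
    noise_ppm: float = 0.0
    #: isotropic Gaussian coordinate perturbation (Angstrom) applied to the
    #: ideal geometry; emulates the coordinate heterogeneity of real models,
    #: which never carry the exact degeneracies of textbook geometry
    coord_noise_A: float = 0.05

    def __post_init__(self):
        if self.length < 4:
            raise ValueError("fixture length must be >= 4")
        if self.kind not in ("helix", "hairpin", "coil", "two-domain"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d given chain a-b-c and internal coords."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(torsion),
                   bond * math.sin(angle) * math.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_from_torsions(phi_psi: list[tuple[float, float]],
                            omega: float = 180.0) -> list[dict]:
    """Backbone N/CA/C/O (+CB) coordinates from a phi/psi list."""
    n_res = len(phi_psi)
    # seed geometry for residue 1
    coords = [{
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([_B["N-CA"], 0.0, 0.0]),
    }]
    coords[0]["C"] = _place(coords[0]["N"] + np.array([0.0, 1.0, 0.0]),
                            coords[0]["N"], coords[0]["CA"],
                            _B["CA-C"], _A["N-CA-C"], phi_psi[0][0] + 180.0)
    for i in range(n_res):
        res = coords[i]
        phi, psi = phi_psi[i]
        if i + 1 < n_res:
            nxt: dict = {}
            nxt["N"] = _place(res["N"], res["CA"], res["C"],
                              _B["C-N"], _A["CA-C-N"], psi)
            nxt["CA"] = _place(res["CA"], res["C"], nxt["N"],
                               _B["N-CA"], _A["C-N-CA"], omega)
            nxt["C"] = _place(res["C"], nxt["N"], nxt["CA"],
                              _B["CA-C"], _A["N-CA-C"], phi_psi[i + 1][0])
            coords.append(nxt)
            res["O"] = _place(nxt["N"], res["CA"], res["C"],
                              _B["C-O"], _A["CA-C-O"], 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"],
                              _B["C-O"], _A["CA-C-O"], psi + 180.0)
        res["CB"] = _place(res["C"], res["N"], res["CA"],
                           _B["CA-CB"], _A["N-CA-CB"], 122.6)
    return coords


def _torsion_schedule(spec: FixtureSpec) -> list[tuple[float, float]]:
    n = spec.length
    if spec.kind == "helix":
        return [TORSIONS["helix"]] * n
    if spec.kind == "hairpin":
        half = (n - 2) // 2
        strand = TORSIONS["strand"]
        sched = [strand] * half + list(TORSIONS["turn"]) \
            + [strand] * (n - half - 2)
        return sched[:n]
    if spec.kind == "two-domain":
        # two helices joined by a flexible extended linker
        h = (n - 4) // 2
        sched = ([TORSIONS["helix"]] * h + [(-120.0, 140.0)] * 4
                 + [TORSIONS["helix"]] * (n - h - 4))
        return sched[:n]
    rng = np.random.default_rng(spec.seed)
    return [(float(rng.uniform(-160.0, -50.0)), float(rng.uniform(-60.0, 170.0)))
            for _ in range(n)]


def make_structure(spec: FixtureSpec) -> Model:
    """Poly-alanine model (N, CA, C, O, CB + backbone amide H) for the spec.

    Heavy atoms receive the seeded coordinate perturbation before amide
    protons are constructed, so the whole model is seed-deterministic.
    """
    coords = _backbone_from_torsions(_torsion_schedule(spec))
    rng = np.random.default_rng(spec.seed + 1_000_003)
    atoms: list[AtomSite] = []
    for i, res in enumerate(coords):
        for name in ("N", "CA", "C", "O", "CB"):
            pos = res[name]
            if spec.coord_noise_A > 0:
                pos = pos + rng.normal(0.0, spec.coord_noise_A, size=3)
            atoms.append(AtomSite(name=name, element=name[0], chain_id="A",
                                  residue_number=i + 1, insertion_code="",
                                  residue_type="ALA", pos=tuple(pos)))
    model = Model(0, atoms)
    return ensure_protons(model, mode="minimal-amide")


def make_shifts(target_flex: np.ndarray,
                rc: RandomCoilTable | None = None,
                weights: WeightTable | None = None,
                restypes: list[str] | None = None,
                seed: int = 0, noise_ppm: float = 0.0,
                chain: str = "A") -> ShiftTable:
    """Shift table whose RCI pipeline output approximates ``target_flex``.

    The target is mapped back through the rescaling (raw = 0.024 + t*0.176)
    and Eq-style inverse (weighted mean = 1/raw); the 3-residue smoothing is
    inverted exactly with a linear solve, and the required secondary-shift
    magnitude is distributed over nuclei with per-nucleus scale factors so
    that proton shifts stay inside physical bounds.  Secondary-shift signs
    alternate along the sequence; seeded Gaussian noise (``noise_ppm``,
    scaled per nucleus) can be added on top.
    """
    rc = rc or RandomCoilTable.default()
    weights = weights or WeightTable.default()
    target = np.asarray(target_flex, dtype=float)
    n = len(target)
    if restypes is None:
        restypes = ["ALA"] * n
    if np.any((target < 0) | (target > 1)):
        raise ValueError("target flexibility must lie in [0, 1]")
    raw = RCI_MODE + target * (RCI_CAP - RCI_MODE)
    mean = 1.0 / raw  # required smoothed weighted mean per residue

    # invert the truncated 3-residue smoothing: solve S d = mean
    smat = np.zeros((n, n))
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        smat[i, lo:hi] = 1.0 / (hi - lo)
    # the truncated-window operator is singular when n % 3 == 2 (a period-3
    # null vector), so use least squares; the unreachable component is tiny
    # for smooth targets
    d = np.linalg.lstsq(smat, mean, rcond=None)[0]
    # sharp target steps can demand negative or unphysically large
    # magnitudes from the deconvolution; clamp to what the physical shift
    # ranges can host (the round trip degrades only at such steps)
    d = np.clip(d, 1e-9, 105.0)

    # per-nucleus share of the secondary-shift magnitude, sized so that even
    # the large magnitudes demanded by sharp target steps stay inside each
    # nucleus's physical shift range
    scale = {"CA": 1.0, "CB": 1.0, "C": 0.4, "N": 0.7, "H": 0.03, "HA": 0.03}
    bounds = {"CA": (0.5, 249.5), "CB": (0.5, 249.5), "C": (0.5, 249.5),
              "N": (0.5, 249.5), "H": (-1.9, 14.9), "HA": (-1.9, 14.9)}
    w = weights.weights_for(frozenset(BACKBONE_NUCLEI))
    sbar = sum(w[k] * scale[nuc] for k, nuc in enumerate(BACKBONE_NUCLEI)) / w.sum()
    lam = d / sbar

    rng = np.random.default_rng(seed)
    table = ShiftTable()
    types3 = restypes
    for i in range(n):
        neighbors = {off: (types3[i + off] if 0 <= i + off < n else None)
                     for off in (-2, -1, 1, 2)}
        sign = 1.0 if i % 2 == 0 else -1.0
        for nuc in BACKBONE_NUCLEI:
            if nuc not in rc.shifts[types3[i]]:
                continue  # Gly CB / Pro H
            ref = rc.reference_shift(types3[i], nuc, neighbors)
            delta = sign * lam[i] * scale[nuc]
            if noise_ppm > 0:
                delta += float(rng.normal(0.0, noise_ppm * scale[nuc]))
            lo, hi = bounds[nuc]
            if not lo < ref + delta < hi:
                delta = -delta  # alternation would leave the physical range
            value = min(max(ref + delta, lo), hi)  # last-resort clamp
            table.add(ShiftRecord(chain, i + 1, types3[i], nuc, value))
    return table


# ---------------------------------------------------------------------------
# brute-force rigidity oracle

_ORACLE_PRIME = 2_147_483_647  # 2^31 - 1


@dataclass
class SimpleGraph:
    """Minimal graph protocol for the rigidity engine and the oracle."""

    n_vertices: int
    bars: list

    @classmethod
    def from_edges(cls, n: int, edges: list[tuple[int, int, int]]):
        from types import SimpleNamespace
        bars = [SimpleNamespace(i=u, j=v, multiplicity=m) for u, v, m in edges]
        return cls(n_vertices=n, bars=bars)


def random_multigraph(rng: np.random.Generator, max_vertices: int = 10,
                      max_bars: int = 40) -> SimpleGraph:
    """Random body-bar multigraph for oracle cross-checks."""
    n = int(rng.integers(2, max_vertices + 1))
    n_bars = int(rng.integers(1, max_bars + 1))
    edges = []
    for _ in range(n_bars):
        u = int(rng.integers(0, n))
        v = int(rng.integers(0, n - 1))
        if v >= u:
            v += 1
        edges.append((min(u, v), max(u, v), 1))
    return SimpleGraph.from_edges(n, edges)


def _counting_rank_and_counts(n: int, bars: list[tuple[int, int]]):
    """Greedy (6,6)-sparsity rank by exhaustive subset counting.

    Returns (rank, cnt, cap, membership) where cnt[s] is the number of
    basis bars inside vertex subset s (bitmask index) and cap[s] = 6|s|-6.
    """
    if n > 12:
        raise ValueError("oracle limited to 12 vertices")
    n_sub = 1 << n
    sizes = np.array([bin(s).count("1") for s in range(n_sub)])
    cap = 6 * sizes - 6
    cnt = np.zeros(n_sub, dtype=np.int64)
    masks = np.arange(n_sub)
    rank = 0
    for u, v in bars:
        both = (masks >> u & 1).astype(bool) & (masks >> v & 1).astype(bool)
        if np.all(cnt[both] + 1 <= cap[both]):
            cnt[both] += 1
            rank += 1
    return rank, cnt, cap, masks


def _matrix_rank_mod_p(n: int, bars: list[tuple[int, int]],
                       rng: np.random.Generator) -> int:
    """Rank of a randomized generic body-bar rigidity matrix over GF(p).

    Each bar contributes one row: the Pluecker coordinates (direction,
    moment) of a random line, entered positively in one body's six columns
    and negatively in the other's.
    """
    p = _ORACLE_PRIME
    rows = np.zeros((len(bars), 6 * n), dtype=np.int64)
    for r, (u, v) in enumerate(bars):
        dvec = rng.integers(1, p, size=3)
        point = rng.integers(1, p, size=3)
        moment = np.cross(point, dvec) % p
        plueck = np.concatenate([dvec % p, moment])
        rows[r, 6 * u:6 * u + 6] = plueck
        rows[r, 6 * v:6 * v + 6] = (-plueck) % p
    # Gaussian elimination over GF(p)
    m = rows % p
    rank = 0
    col = 0
    n_rows, n_cols = m.shape
    while rank < n_rows and col < n_cols:
        piv = np.nonzero(m[rank:, col])[0]
        if len(piv) == 0:
            col += 1
            continue
        r0 = rank + piv[0]
        m[[rank, r0]] = m[[r0, rank]]
        inv = pow(int(m[rank, col]), p - 2, p)
        m[rank] = m[rank] * inv % p
        other = np.nonzero(m[:, col])[0]
        other = other[other != rank]
        if len(other):
            m[other] = (m[other] - np.outer(m[other, col], m[rank])) % p
        rank += 1
        col += 1
    return rank


def oracle_dof(graph, rng: np.random.Generator | None = None):
    """Brute-force DOF and rigid clusters for a small multigraph.

    The (6,6) counting rank and the randomized Pluecker-matrix rank over a
    prime field must agree; mutual rigidity of a vertex pair is read off as
    the existence of a tight subset containing both, and clusters are the
    classes of that relation.  Returns ``(dof, clusters)`` with clusters a
    set of frozensets.  Refuses graphs with more than 12 vertices.
    """
    rng = rng or np.random.default_rng(0)
    n = graph.n_vertices
    bars = []
    for b in graph.bars:
        bars.extend([(b.i, b.j)] * b.multiplicity)
    rank_count, cnt, cap, masks = _counting_rank_and_counts(n, bars)
    rank_matrix = _matrix_rank_mod_p(n, bars, rng)
    if rank_count != rank_matrix:
        raise AssertionError(
            f"oracle disagreement: counting rank {rank_count} vs "
            f"matrix rank {rank_matrix}")
    dof = 6 * n - rank_count

    tight = (cnt == cap) & (np.array([bin(s).count("1") for s in range(1 << n)]) >= 2)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n):
        for v in range(u + 1, n):
            both = (masks >> u & 1).astype(bool) & (masks >> v & 1).astype(bool)
            if np.any(tight & both):
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[max(ru, rv)] = min(ru, rv)
    clusters: dict[int, set] = {}
    for v in range(n):
        clusters.setdefault(find(v), set()).add(v)
    return dof, {frozenset(s) for s in clusters.values()}
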
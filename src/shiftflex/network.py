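"""Body-bar constraint network for rigidity analysis.

Every atom is a rigid body with six degrees of freedom.  Interactions are
multi-edges ("bars") between atoms: five bars for a rotatable single
covalent bond, six for double/partial-double/delocalized bonds (peptide
bonds, carboxylates, amides, guanidinium, aromatic rings), five for a
hydrogen bond that passes the energy cutoff, and two for a hydrophobic
tether.

Hydrogen-bond energies use a Mayo-style potential

    E = V0 * (5 (d0/d)^12 - 6 (d0/d)^10) * F(theta, phi)

with V0 = 8 kcal/mol and d0 = 2.8 A, d the donor-acceptor distance, and F
an angular factor in [0, 1] built from the donor-H-acceptor angle theta
(ideal 180 deg) and the H-acceptor-base angle phi (ideal 109.5 deg for sp3
acceptors, 120 deg for sp2).  Only the ordering of energies matters for
the dilution analysis, so the exact functional form is isolated here and
can be swapped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._aminoacids import (VDW_RADII, acceptor_hybridization, hydrogen_parent,
                          residue_bonds)
from .structure import EmptyStructureError, Model

HB_V0 = 8.0       # kcal/mol
HB_D0 = 2.8       # Angstrom
HB_DEFAULT_CUTOFF = -0.01   # kcal/mol; weaker bonds are ignored
HB_DISTANCE_SCREEN = 5.0    # donor-acceptor distance screen, Angstrom
HYDROPHOBIC_SLACK = 0.25    # added to vdW radii sum, Angstrom

BARS_SINGLE = 5
BARS_DOUBLE = 6
BARS_HBOND = 5
BARS_HYDROPHOBIC = 2


@dataclass(frozen=True)
class Bar:
    """A multi-edge between two atom bodies."""

    i: int
    j: int
    multiplicity: int
    kind: str  # single-covalent | double-covalent | hbond | hydrophobic
    energy_kcal: float | None = None

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-edges are not allowed")
        expected = {"single-covalent": BARS_SINGLE, "double-covalent": BARS_DOUBLE,
                    "hbond": BARS_HBOND, "hydrophobic": BARS_HYDROPHOBIC}
        if self.kind not in expected:
            raise ValueError(f"unknown bar kind {self.kind!r}")
        if self.multiplicity != expected[self.kind]:
            raise ValueError(f"{self.kind} bars must have multiplicity "
                             f"{expected[self.kind]}")
        if self.kind == "hbond":
            if self.energy_kcal is None or not math.isfinite(self.energy_kcal):
                raise ValueError("hbond bars need a finite energy")


@dataclass
class ConstraintGraph:
    """Atoms as bodies, bars as constraints, plus the atom-residue index."""

    n_vertices: int
    bars: list[Bar]
    atom_residue: list[int]                  # residue index per atom
    residue_ids: list[tuple[str, int, str]]  # author ids per residue index
    ca_atoms: dict[int, int | None]          # residue index -> CA atom index

    @property
    def hbond_bars(self) -> list[Bar]:
        """Hydrogen-bond bars sorted weakest (least negative) first."""
        return sorted((b for b in self.bars if b.kind == "hbond"),
                      key=lambda b: (-b.energy_kcal, b.i, b.j))

    def bars_at_cutoff(self, cutoff: float | None) -> list[Bar]:
        """Bars present when hbonds with energy above ``cutoff`` are removed;
        ``cutoff=None`` removes every hydrogen bond."""
        out = []
        for b in self.bars:
            if b.kind == "hbond":
                if cutoff is None or b.energy_kcal > cutoff:
                    continue
            out.append(b)
        return out


# ---------------------------------------------------------------------------
# covalent topology

def _covalent_topology(model: Model):
    """Heavy-atom + hydrogen bond list [(i, j, order)] from templates.

    Unknown atoms are connected to the nearest template atom in the same
    residue with a warning (single bond).
    """
    bonds: list[tuple[int, int, int]] = []
    coords = model.coords()
    for rid in model.residues:
        restype = model.residue_type(rid)
        idxs = model.residue_atoms(rid)
        by_name = {model.atoms[i].name: i for i in idxs}
        heavy_names = {model.atoms[i].name for i in idxs
                       if model.atoms[i].element != "H"}
        template = residue_bonds(restype)
        templated = set()
        for a, b, order in template:
            templated.update((a, b))
            if a in by_name and b in by_name:
                bonds.append((by_name[a], by_name[b], order))
        # carboxy-terminal OXT: delocalized with C=O
        if "OXT" in by_name and "C" in by_name:
            bonds.append((by_name["C"], by_name["OXT"], 2))
            templated.add("OXT")
        for i in idxs:
            atom = model.atoms[i]
            if atom.element == "H":
                parent = hydrogen_parent(atom.name, heavy_names)
                if parent is not None and parent in by_name:
                    bonds.append((by_name[parent], i, 1))
                    continue
            elif atom.name in templated:
                continue
            # fall back: tie to the nearest heavy atom of the residue
            others = [j for j in idxs
                      if j != i and model.atoms[j].element != "H"]
            if not others:
                continue
            d = np.linalg.norm(coords[others] - coords[i], axis=1)
            j = others[int(np.argmin(d))]
            warnings.warn(f"atom {atom.name} of {restype}{rid[1]} not in "
                          "template; connected to nearest heavy atom")
            bonds.append((j, i, 1))
    # inter-residue peptide bonds (partial double -> locked)
    for chain in model.chains:
        rids = model.chain_residues(chain)
        for prev, rid in zip(rids, rids[1:]):
            c = model.atom_index(prev, "C")
            n = model.atom_index(rid, "N")
            if c is None or n is None:
                continue
            if np.linalg.norm(coords[c] - coords[n]) < 2.5:
                bonds.append((c, n, 2))
    # disulfides
    sg = [i for i, a in enumerate(model.atoms)
          if a.name == "SG" and a.residue_type == "CYS"]
    for ii, i in enumerate(sg):
        for j in sg[ii + 1:]:
            if np.linalg.norm(coords[i] - coords[j]) < 2.5:
                bonds.append((i, j, 1))
    return bonds


def covalent_bars(model: Model) -> list[Bar]:
    """Covalent bars: 5 per rotatable single bond, 6 per locked bond."""
    bars = []
    for i, j, order in _covalent_topology(model):
        a, b = (i, j) if i < j else (j, i)
        if order == 2:
            bars.append(Bar(a, b, BARS_DOUBLE, "double-covalent"))
        else:
            bars.append(Bar(a, b, BARS_SINGLE, "single-covalent"))
    return bars


# ---------------------------------------------------------------------------
# hydrogen bonds

def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u, v = a - b, c - b
    cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.acos(max(-1.0, min(1.0, cosang)))


def hbond_energy(donor_xyz, hydrogen_xyz, acceptor_xyz,
                 base_xyz=None, acceptor_hybrid: str = "sp2",
                 v0: float = HB_V0, d0: float = HB_D0) -> float:
    """Mayo-style hydrogen-bond energy in kcal/mol (negative = favourable).

    Returns 0.0 for geometries that cannot form a bond (theta <= 90 deg).
    Degenerate colinear geometries are evaluated by limit, not rejected.
    """
    donor_xyz = np.asarray(donor_xyz, float)
    hydrogen_xyz = np.asarray(hydrogen_xyz, float)
    acceptor_xyz = np.asarray(acceptor_xyz, float)
    d = float(np.linalg.norm(donor_xyz - acceptor_xyz))
    if d < 1e-6:
        return 0.0
    radial = v0 * (5.0 * (d0 / d) ** 12 - 6.0 * (d0 / d) ** 10)
    theta = _angle(donor_xyz, hydrogen_xyz, acceptor_xyz)
    if theta <= math.pi / 2:
        return 0.0
    f = math.cos(theta) ** 2 * math.exp(-((math.pi - theta) ** 6))
    if base_xyz is not None:
        phi = _angle(hydrogen_xyz, acceptor_xyz, np.asarray(base_xyz, float))
        phi0 = math.radians(109.5 if acceptor_hybrid == "sp3" else 120.0)
        f *= math.cos(phi - phi0) ** 2
    return radial * max(0.0, min(1.0, f))


def _polar_atoms(model: Model, topology):
    """Donor (with hydrogens) and acceptor candidates among N/O/S atoms."""
    neighbors: dict[int, list[int]] = {}
    for i, j, _ in topology:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    donors = {}      # heavy atom -> list of bonded H
    acceptors = []   # heavy atoms with lone pairs (all N/O/S here)
    for i, a in enumerate(model.atoms):
        if a.element not in ("N", "O", "S"):
            continue
        hs = [j for j in neighbors.get(i, [])
              if model.atoms[j].element == "H"]
        if hs:
            donors[i] = sorted(hs)
        # protonated nitrogens (amide/ammonium) have no usable lone pair
        if a.element == "N" and hs:
            continue
        acceptors.append(i)
    return donors, acceptors, neighbors


def detect_hbonds(model: Model, include_cutoff: float = HB_DEFAULT_CUTOFF,
                  topology=None) -> list[Bar]:
    """Hydrogen-bond bars (5 each, between H and acceptor).

    All N/O/S donor-H ... N/O/S acceptor pairs within the 5 A screen are
    scored with :func:`hbond_energy`; pairs at or below ``include_cutoff``
    become bars.  Salt-bridge pairs pass through the same energy function.
    """
    if topology is None:
        topology = _covalent_topology(model)
    donors, acceptors, neighbors = _polar_atoms(model, topology)
    if not donors or not acceptors:
        return []
    coords = model.coords()
    acc_arr = np.array(acceptors)
    tree = cKDTree(coords[acc_arr])
    bars = []
    for d_idx in sorted(donors):
        for a_local in tree.query_ball_point(coords[d_idx], HB_DISTANCE_SCREEN):
            a_idx = int(acc_arr[a_local])
            if a_idx == d_idx:
                continue
            # skip covalently bonded or geminal pairs
            if a_idx in neighbors.get(d_idx, []):
                continue
            if any(a_idx in neighbors.get(m, []) for m in neighbors.get(d_idx, [])):
                continue
            acc = model.atoms[a_idx]
            bases = [m for m in neighbors.get(a_idx, [])
                     if model.atoms[m].element != "H"]
            base_xyz = coords[bases[0]] if bases else None
            hybrid = acceptor_hybridization(acc.residue_type, acc.name)
            best = (0.0, None)
            for h_idx in donors[d_idx]:
                e = hbond_energy(coords[d_idx], coords[h_idx], coords[a_idx],
                                 base_xyz, hybrid)
                if e < best[0]:
                    best = (e, h_idx)
            if best[1] is not None and best[0] <= include_cutoff:
                i, j = sorted((best[1], a_idx))
                bars.append(Bar(i, j, BARS_HBOND, "hbond",
                                energy_kcal=best[0]))
    bars.sort(key=lambda b: (b.energy_kcal, b.i, b.j))
    return bars


# ---------------------------------------------------------------------------
# hydrophobic tethers

def detect_hydrophobics(model: Model, topology=None,
                        slack: float = HYDROPHOBIC_SLACK) -> list[Bar]:
    """2-bar tethers between apolar C/S atoms at van der Waals contact.

    Both atoms must be bonded only to C, S or H, the pair within
    r_vdw(a)+r_vdw(b)+slack, and at least three covalent bonds apart.
    """
    if topology is None:
        topology = _covalent_topology(model)
    neighbors: dict[int, set[int]] = {}
    for i, j, _ in topology:
        neighbors.setdefault(i, set()).add(j)
        neighbors.setdefault(j, set()).add(i)

    def apolar(i):
        a = model.atoms[i]
        if a.element not in ("C", "S"):
            return False
        return all(model.atoms[j].element in ("C", "S", "H")
                   for j in neighbors.get(i, ()))

    cand = [i for i in range(len(model.atoms)) if apolar(i)]
    if len(cand) < 2:
        return []
    coords = model.coords()
    tree = cKDTree(coords[cand])
    max_r = 2 * max(VDW_RADII["C"], VDW_RADII["S"]) + slack
    bars = []
    for ii, jj in sorted(tree.query_pairs(max_r)):
        i, j = cand[ii], cand[jj]
        ra = VDW_RADII[model.atoms[i].element]
        rb = VDW_RADII[model.atoms[j].element]
        if np.linalg.norm(coords[i] - coords[j]) > ra + rb + slack:
            continue
        # exclude pairs closer than 3 covalent bonds
        frontier = {i}
        seen = {i}
        near = False
        for _ in range(2):
            frontier = set().union(*(neighbors.get(x, set()) for x in frontier)) - seen
            if j in frontier:
                near = True
                break
            seen |= frontier
        if near:
            continue
        a, b = (i, j) if i < j else (j, i)
        bars.append(Bar(a, b, BARS_HYDROPHOBIC, "hydrophobic"))
    return bars


# ---------------------------------------------------------------------------

def build_graph(model: Model, include_cutoff: float = HB_DEFAULT_CUTOFF,
                hydrophobics: bool = True) -> ConstraintGraph:
    """Assemble the full constraint network for one model."""
    if not model.atoms:
        raise EmptyStructureError("model has no atoms")
    topology = _covalent_topology(model)
    bars = covalent_bars(model)
    bars += detect_hbonds(model, include_cutoff, topology=topology)
    if hydrophobics:
        bars += detect_hydrophobics(model, topology=topology)
    residue_ids = model.residues
    rindex = {rid: k for k, rid in enumerate(residue_ids)}
    atom_residue = [rindex[a.residue_id] for a in model.atoms]
    ca_atoms = {k: model.atom_index(rid, "CA")
                for rid, k in rindex.items()}
    return ConstraintGraph(n_vertices=len(model.atoms), bars=bars,
                           atom_residue=atom_residue, residue_ids=residue_ids,
                           ca_atoms=ca_atoms)
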
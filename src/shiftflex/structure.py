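"""Coordinate input and normalization for PDB/mmCIF ensembles.

Models are read with gemmi and reduced to protein atoms only.  For
alternate-conformation groups only the first-listed conformer is retained;
waters and non-protein heteroatoms are dropped; selenomethionine and a few
other standard-parent modifications are remapped to their parent residue
type without touching coordinates.  A minimal amide-proton builder is
provided for structures deposited without hydrogens (full protonation with
rotamer optimization is treated as external preprocessing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._aminoacids import PARENT_RESIDUE, STANDARD_RESIDUES, THREE_TO_ONE


class EmptyStructureError(ValueError):
    """No protein atoms found in the coordinate file."""


class ProtonError(ValueError):
    """Hydrogens required but absent, or amide H cannot be constructed."""


class ResidueMismatchError(ValueError):
    """Structure and shift-table sequences cannot be reconciled."""


@dataclass(frozen=True)
class AtomSite:
    """One atom with author residue identifiers."""

    name: str
    element: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_type: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos)


@dataclass
class Model:
    """One coordinate model: a flat atom list plus residue bookkeeping."""

    index: int
    atoms: list[AtomSite] = field(default_factory=list)

    def __post_init__(self):
        self._reindex()

    def _reindex(self):
        self._by_key: dict[tuple, int] = {}
        self._residues: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
            if key in self._by_key:
                raise ValueError(f"duplicate atom after normalization: {key}")
            self._by_key[key] = i
            self._residues.setdefault(a.residue_id, []).append(i)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """Residue ids in file order."""
        return list(self._residues)

    def chain_residues(self, chain: str) -> list[tuple[str, int, str]]:
        return [r for r in self._residues if r[0] == chain]

    @property
    def chains(self) -> list[str]:
        seen = dict.fromkeys(a.chain_id for a in self.atoms)
        return list(seen)

    def residue_type(self, rid: tuple[str, int, str]) -> str:
        return self.atoms[self._residues[rid][0]].residue_type

    def residue_atoms(self, rid: tuple[str, int, str]) -> list[int]:
        return self._residues[rid]

    def atom_index(self, rid: tuple[str, int, str], name: str) -> int | None:
        return self._by_key.get((rid[0], rid[1], rid[2], name))

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def sequence(self, chain: str) -> str:
        return "".join(THREE_TO_ONE.get(self.residue_type(r), "X")
                       for r in self.chain_residues(chain))

    def with_atoms(self, atoms: list[AtomSite], index: int | None = None) -> "Model":
        return Model(self.index if index is None else index, atoms)


def read_models(path: str | Path) -> list[Model]:
    """Read a PDB or mmCIF file into normalized models.

    One :class:`Model` per coordinate model; first-listed altloc conformer
    kept; waters and non-protein heteroatoms dropped; standard-parent
    modified residues remapped.  Raises :class:`EmptyStructureError` when no
    protein atoms remain.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models: list[Model] = []
    for mi, gmodel in enumerate(st):
        atoms: list[AtomSite] = []
        for chain in gmodel:
            for res in chain:
                if res.is_water():
                    continue
                rname = res.name.strip().upper()
                if rname in PARENT_RESIDUE:
                    rname = PARENT_RESIDUE[rname]
                if rname not in STANDARD_RESIDUES:
                    # non-protein heteroatom group: drop silently
                    continue
                first_alt: dict[str, str] = {}
                for atom in res:
                    alt = atom.altloc if atom.altloc not in ("\x00",) else ""
                    name = atom.name.strip()
                    if name == "SE" and res.name.strip().upper() == "MSE":
                        name = "SD"
                    if alt:
                        kept = first_alt.setdefault(name, alt)
                        if alt != kept:
                            continue
                    elif name in first_alt:
                        continue
                    else:
                        first_alt[name] = ""
                    el = atom.element.name.upper() if atom.element else ""
                    if el == "SE":
                        el = "S"
                    if not el:
                        el = name[0]
                    atoms.append(AtomSite(
                        name=name, element=el, chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_type=rname,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ))
        if atoms:
            models.append(Model(mi, atoms))
    if not models:
        raise EmptyStructureError(f"{path}: no protein atoms found")
    return models


def _place_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray,
                   bond: float = 1.01) -> np.ndarray:
    """Amide H on the C(i-1)-N-CA bisector, trans to the preceding carbonyl."""
    u1 = c_prev - n
    u2 = ca - n
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    d = -(u1 + u2)
    nrm = np.linalg.norm(d)
    if nrm < 1e-8:  # colinear degenerate case: any perpendicular direction
        probe = np.array([1.0, 0.0, 0.0])
        d = np.cross(u1, probe)
        if np.linalg.norm(d) < 1e-8:
            d = np.cross(u1, np.array([0.0, 1.0, 0.0]))
        nrm = np.linalg.norm(d)
    return n + bond * d / nrm


def ensure_protons(model: Model, mode: str = "require") -> Model:
    """Check or minimally complete amide protonation.

    ``mode="require"`` raises :class:`ProtonError` listing every non-proline
    residue (beyond the chain start) lacking an amide H.  With
    ``mode="minimal-amide"`` a missing amide H is placed 1.01 A from N in
    the C(i-1)-N-CA plane, trans to the preceding carbonyl O.  Existing
    atoms are never moved.
    """
    if mode not in ("require", "minimal-amide"):
        raise ValueError(f"unknown proton mode {mode!r}")
    missing: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = []
    for chain in model.chains:
        rids = model.chain_residues(chain)
        for prev, rid in zip(rids, rids[1:]):
            if model.residue_type(rid) == "PRO":
                continue
            if model.atom_index(rid, "H") is not None \
                    or model.atom_index(rid, "HN") is not None:
                continue
            missing.append((prev, rid))
    if not missing:
        return model
    if mode == "require":
        names = ", ".join(f"{r[0]}{r[1]}{r[2]}" for _, r in missing)
        raise ProtonError(f"amide H missing for residues: {names}")
    new_atoms = list(model.atoms)
    for prev, rid in missing:
        idx = {nm: model.atom_index(rid, nm) for nm in ("N", "CA")}
        cprev = model.atom_index(prev, "C")
        if None in idx.values() or cprev is None:
            raise ProtonError(
                f"cannot place amide H for {rid}: backbone heavy atoms missing")
        h = _place_amide_h(model.atoms[idx["N"]].xyz,
                           model.atoms[idx["CA"]].xyz,
                           model.atoms[cprev].xyz)
        new_atoms.append(AtomSite("H", "H", rid[0], rid[1], rid[2],
                                  model.residue_type(rid), tuple(h)))
    return model.with_atoms(new_atoms)


@dataclass
class ResidueMap:
    """One-to-one mapping between structure residues and shift residues."""

    pairs: list[tuple[tuple[str, int, str], tuple[str, int]]]
    unmapped_structure: list[tuple[str, int, str]]
    unmapped_shifts: list[tuple[str, int]]

    def shift_residue(self, rid: tuple[str, int, str]) -> tuple[str, int] | None:
        return dict(self.pairs).get(rid)

    def __len__(self) -> int:
        return len(self.pairs)


def map_residues(model: Model, shifts, chain: str | None = None,
                 shift_chain: str | None = None) -> ResidueMap:
    """Match structure residues to shift-table residues.

    Author numbering is used directly when number+type agree for at least
    90% of shift residues; otherwise the one-letter sequences are globally
    aligned (identity scoring) and identical aligned positions are mapped.
    Raises :class:`ResidueMismatchError` below 50% alignment identity.
    """
    chain = chain or model.chains[0]
    shift_chain = shift_chain or (chain if chain in shifts.chains
                                  else shifts.chains[0])
    struct_res = model.chain_residues(chain)
    shift_res = [(c, n, t) for c, n, t in shifts.residues(shift_chain)]
    if not struct_res or not shift_res:
        raise ResidueMismatchError("empty structure or shift sequence")

    struct_types = {(r[1]): model.residue_type(r) for r in struct_res}
    direct = [(r, (shift_chain, n)) for r in struct_res
              for c, n, t in shift_res
              if n == r[1] and r[2] == "" and struct_types[r[1]] == t]
    if len(direct) >= 0.9 * len(shift_res):
        mapped_struct = {p[0] for p in direct}
        mapped_shift = {p[1] for p in direct}
        return ResidueMap(
            pairs=direct,
            unmapped_structure=[r for r in struct_res if r not in mapped_struct],
            unmapped_shifts=[(c, n) for c, n, _ in shift_res
                             if (c, n) not in mapped_shift])

    from Bio import Align

    seq_a = model.sequence(chain)
    nums_b = sorted(n for _, n, _ in shift_res)
    type_b = {n: t for _, n, t in shift_res}
    full_b = list(range(nums_b[0], nums_b[-1] + 1))
    seq_b = "".join(THREE_TO_ONE.get(type_b.get(n, ""), "X") for n in full_b)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    identical = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for off in range(a1 - a0):
            ia, ib = a0 + off, b0 + off
            aligned_cols += 1
            if seq_a[ia] == seq_b[ib] and seq_a[ia] != "X":
                identical += 1
                num_b = full_b[ib]
                if num_b in type_b:  # only residues actually in the table
                    pairs.append((struct_res[ia], (shift_chain, num_b)))
    identity = identical / max(1, min(len(seq_a), len(seq_b)))
    if identity < 0.5:
        raise ResidueMismatchError(
            f"sequence identity {identity:.0%} below 50%: wrong shift file?")
    mapped_struct = {p[0] for p in pairs}
    mapped_shift = {p[1] for p in pairs}
    return ResidueMap(
        pairs=pairs,
        unmapped_structure=[r for r in struct_res if r not in mapped_struct],
        unmapped_shifts=[(c, n) for c, n, _ in shift_res
                         if (c, n) not in mapped_shift])


# ---------------------------------------------------------------------------
# plain-text PDB writing (fixtures, round-trip tests)

def write_pdb(models: list[Model] | Model, path: str | Path) -> None:
    """Write models as a (multi-MODEL) PDB text file."""
    if isinstance(models, Model):
        models = [models]
    lines = []
    multi = len(models) > 1
    for mi, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {mi:4d}")
        serial = 1
        for a in model.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{'':1s}{a.residue_type:>3s} "
                f"{a.chain_id[:1]:1s}{a.residue_number:4d}{a.insertion_code:1s}"
                f"   {a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}")
            serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
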
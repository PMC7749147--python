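"""Structure reading, altloc/water handling, protonation, residue mapping."""

import numpy as np
import pytest

from shiftflex.fixtures import FixtureSpec, make_structure
from shiftflex.shifts import ShiftRecord, ShiftTable
from shiftflex.structure import (EmptyStructureError, ProtonError,
                                 ResidueMismatchError, ensure_protons,
                                 map_residues, read_models, write_pdb)

PDB_TWO_MODEL = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
TER
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.109   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.351   2.390   0.000  1.00  0.00           O
TER
ENDMDL
END
"""

PDB_ALTLOC_WATER = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.400   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
HETATM    6  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
HETATM    7  O   HOH A 102       6.000   6.000   6.000  1.00  0.00           O
END
"""


class TestReadModels:
    def test_two_model_ensemble(self, tmp_path):
        path = tmp_path / "ens.pdb"
        path.write_text(PDB_TWO_MODEL)
        models = read_models(path)
        assert len(models) == 2
        assert [len(m.atoms) for m in models] == [4, 4]

    def test_first_altloc_kept_and_waters_dropped(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(PDB_ALTLOC_WATER)
        (model,) = read_models(path)
        cas = [a for a in model.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].pos[0] == pytest.approx(1.458)  # conformer A
        assert all(a.residue_type != "HOH" for a in model.atoms)
        assert len(model.atoms) == 4

    def test_no_protein_atoms_is_error(self, tmp_path):
        path = tmp_path / "wat.pdb"
        path.write_text("HETATM    1  O   HOH A   1       0.0     0.0     0.0"
                        "  1.00  0.00           O\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_models(path)

    def test_roundtrip_is_idempotent(self, tmp_path, helix20):
        write_pdb(helix20, tmp_path / "a.pdb")
        (m1,) = read_models(tmp_path / "a.pdb")
        write_pdb(m1, tmp_path / "b.pdb")
        (m2,) = read_models(tmp_path / "b.pdb")
        assert [a.name for a in m1.atoms] == [a.name for a in m2.atoms]
        assert np.allclose(m1.coords(), m2.coords(), atol=1e-3)


def _strip_protons(model):
    return model.with_atoms([a for a in model.atoms if a.element != "H"])


class TestEnsureProtons:
    def test_protonated_model_unchanged(self, helix20):
        out = ensure_protons(helix20, mode="require")
        assert out is helix20

    def test_require_mode_lists_missing_residues(self, helix20):
        bare = _strip_protons(helix20)
        with pytest.raises(ProtonError, match="A2"):
            ensure_protons(bare, mode="require")

    def test_minimal_amide_geometry(self):
        # ideal (noise-free) geometry: the bisector construction must put H
        # exactly trans to the preceding carbonyl O
        ideal = make_structure(FixtureSpec("helix", length=20,
                                           coord_noise_A=0.0))
        bare = _strip_protons(ideal)
        out = ensure_protons(bare, mode="minimal-amide")
        for i in range(2, 21):
            rid = ("A", i, "")
            h = out.atoms[out.atom_index(rid, "H")].xyz
            n = out.atoms[out.atom_index(rid, "N")].xyz
            assert np.linalg.norm(h - n) == pytest.approx(1.01, abs=1e-9)
            # trans to the preceding carbonyl O: dihedral H-N-C(i-1)-O ~ 180
            c = out.atoms[out.atom_index(("A", i - 1, ""), "C")].xyz
            o = out.atoms[out.atom_index(("A", i - 1, ""), "O")].xyz
            b0, b1, b2 = n - h, c - n, o - c
            b1u = b1 / np.linalg.norm(b1)
            v = -b0 - (-b0 @ b1u) * b1u
            w = b2 - (b2 @ b1u) * b1u
            ang = np.degrees(np.arctan2(np.cross(b1u, v) @ w, v @ w))
            assert abs(abs(ang) - 180.0) < 1.0

    def test_never_moves_existing_atoms(self, helix20):
        bare = _strip_protons(helix20)
        out = ensure_protons(bare, mode="minimal-amide")
        heavy_in = [a for a in bare.atoms]
        heavy_out = [a for a in out.atoms if a.element != "H"]
        assert [a.pos for a in heavy_in] == [a.pos for a in heavy_out]


def _shift_table_for(model, offset=0):
    table = ShiftTable()
    for rid in model.residues:
        table.add(ShiftRecord("A", rid[1] + offset, model.residue_type(rid),
                              "CA", 52.0))
    return table


class TestMapResidues:
    def test_identical_numbering_full_map(self, helix20):
        rmap = map_residues(helix20, _shift_table_for(helix20))
        assert len(rmap) == 20
        assert not rmap.unmapped_structure and not rmap.unmapped_shifts

    def test_offset_numbering_recovered_by_alignment(self, helix20):
        # poly-Ala aligns at any offset; mapping must be complete and 1:1
        rmap = map_residues(helix20, _shift_table_for(helix20, offset=5))
        assert len(rmap) == 20
        mapped_shift = [s for _, s in rmap.pairs]
        assert len(set(mapped_shift)) == len(mapped_shift)

    def test_unrelated_sequences_raise(self, helix20):
        table = ShiftTable()
        for i, rt in enumerate(["TRP", "PHE", "TYR", "LYS", "GLU", "SER",
                                "THR", "ASN", "GLN", "HIS"]):
            table.add(ShiftRecord("A", i + 1, rt, "CA", 55.0))
        with pytest.raises(ResidueMismatchError):
            map_residues(helix20, table)

    def test_mapped_pairs_have_identical_types(self, helix20):
        rmap = map_residues(helix20, _shift_table_for(helix20))
        table = _shift_table_for(helix20)
        types = {(c, n): t for c, n, t in table.residues()}
        for struct_rid, shift_key in rmap.pairs:
            assert helix20.residue_type(struct_rid) == types[shift_key]
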
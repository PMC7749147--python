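"""Reading and normalizing backbone chemical-shift assignments.

Two input dialects are supported: the assigned-chemical-shift loop of
NMR-STAR 3.1 files (the BMRB deposition format) and a plain tab-separated
table with columns ``chain residue_number residue_type atom shift_ppm``.
Both are normalized to the same :class:`ShiftTable` of backbone shifts
(CA, CB, C', N, HN, HA), with glycine HA2/HA3 averaged into a single HA
record.

Shift completeness is the fraction of expected backbone shifts that are
assigned.  The expected set is {CA, CB, C, N, H, HA} minus CB for glycine
and minus H for proline; the N and H of the first residue of each chain
are excluded from the denominator because they are rarely observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._aminoacids import ONE_TO_THREE, STANDARD_RESIDUES, THREE_TO_ONE

BACKBONE_NUCLEI = ("CA", "CB", "C", "N", "H", "HA")

# atom-name synonyms normalized on input
_ATOM_ALIASES = {"HN": "H", "C'": "C", "CO": "C", "15N": "N"}


class ShiftFormatError(ValueError):
    """Input file could not be parsed as chemical-shift assignments."""


class EmptyShiftTableError(ValueError):
    """No backbone shifts found in the input."""


class ShiftConflictError(ValueError):
    """Duplicate (chain, residue, nucleus) entries with differing values."""


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned backbone chemical shift."""

    chain_id: str
    residue_number: int
    residue_type: str  # 3-letter code
    nucleus: str       # one of BACKBONE_NUCLEI
    shift_ppm: float

    def __post_init__(self):
        if self.nucleus not in BACKBONE_NUCLEI:
            raise ValueError(f"not a backbone nucleus: {self.nucleus!r}")
        object.__setattr__(self, "shift_ppm", float(self.shift_ppm))
        object.__setattr__(self, "residue_number", int(self.residue_number))
        v = self.shift_ppm
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("shift must be finite")
        if self.nucleus in ("H", "HA"):
            if not -2.0 < v < 15.0:
                raise ValueError(
                    f"proton shift {v} ppm outside (-2, 15) for "
                    f"{self.residue_type}{self.residue_number} {self.nucleus}")
        else:
            if not 0.0 < v < 250.0:
                raise ValueError(
                    f"heavy-atom shift {v} ppm outside (0, 250) for "
                    f"{self.residue_type}{self.residue_number} {self.nucleus}")


@dataclass
class ShiftTable:
    """Normalized per-residue, per-nucleus backbone shift assignments."""

    records: dict[tuple[str, int, str], ShiftRecord] = field(default_factory=dict)

    def add(self, rec: ShiftRecord) -> None:
        key = (rec.chain_id, rec.residue_number, rec.nucleus)
        old = self.records.get(key)
        if old is not None and abs(old.shift_ppm - rec.shift_ppm) > 1e-6:
            raise ShiftConflictError(
                f"conflicting values for {key}: {old.shift_ppm} vs {rec.shift_ppm}")
        self.records[key] = rec

    def get(self, chain: str, resnum: int, nucleus: str) -> float | None:
        rec = self.records.get((chain, resnum, nucleus))
        return None if rec is None else rec.shift_ppm

    @property
    def chains(self) -> list[str]:
        return sorted({r.chain_id for r in self.records.values()})

    def residues(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        """Sorted (chain, residue number, residue type) with any assignment."""
        seen: dict[tuple[str, int], str] = {}
        for rec in self.records.values():
            if chain is not None and rec.chain_id != chain:
                continue
            seen[(rec.chain_id, rec.residue_number)] = rec.residue_type
        return [(c, n, t) for (c, n), t in sorted(seen.items())]

    def sequence(self, chain: str) -> str:
        """One-letter sequence inferred from assigned residues (gaps as X)."""
        res = self.residues(chain)
        if not res:
            return ""
        nums = [n for _, n, _ in res]
        types = {n: t for _, n, t in res}
        out = []
        for n in range(min(nums), max(nums) + 1):
            out.append(THREE_TO_ONE.get(types.get(n, ""), "X"))
        return "".join(out)

    def assigned_nuclei(self, chain: str, resnum: int) -> frozenset[str]:
        return frozenset(
            nuc for nuc in BACKBONE_NUCLEI
            if (chain, resnum, nuc) in self.records)

    @property
    def completeness(self) -> float:
        return completeness(self)

    def __len__(self) -> int:
        return len(self.records)


def expected_nuclei(restype: str, first_in_chain: bool = False) -> set[str]:
    """Expected backbone nuclei for one residue (Gly lacks CB, Pro lacks H)."""
    exp = set(BACKBONE_NUCLEI)
    if restype == "GLY":
        exp.discard("CB")
    if restype == "PRO":
        exp.discard("H")
    if first_in_chain:
        exp -= {"N", "H"}
    return exp


def completeness(table: ShiftTable,
                 sequence: list[tuple[str, int, str]] | None = None) -> float:
    """Fraction of expected backbone shifts that are assigned.

    ``sequence`` may supply the full residue list (chain, number, type) from
    a structure; otherwise only residues with at least one assignment are
    counted, which makes the denominator a lower bound.
    """
    residues = sequence if sequence is not None else table.residues()
    if not residues:
        raise EmptyShiftTableError("shift table has no residues")
    first_of_chain = {}
    for c, n, _ in residues:
        first_of_chain.setdefault(c, n)
    expected = 0
    assigned = 0
    for c, n, t in residues:
        exp = expected_nuclei(t, first_in_chain=(first_of_chain[c] == n))
        expected += len(exp)
        assigned += len(exp & set(table.assigned_nuclei(c, n)))
    return assigned / expected if expected else 0.0


def _normalize_restype(raw: str) -> str | None:
    raw = raw.strip().upper()
    if len(raw) == 1:
        raw = ONE_TO_THREE.get(raw, raw)
    return raw if raw in STANDARD_RESIDUES else None


def _build_table(rows: list[tuple[str, int, str, str, float]]) -> ShiftTable:
    """Normalize raw (chain, resnum, restype, atom, value) rows to a table.

    Non-backbone atoms are dropped; Gly HA2/HA3 pairs are averaged to HA.
    """
    table = ShiftTable()
    gly_ha: dict[tuple[str, int, str], list[float]] = {}
    for chain, resnum, restype_raw, atom_raw, value in rows:
        restype = _normalize_restype(restype_raw)
        if restype is None:
            warnings.warn(f"skipping non-standard residue type {restype_raw!r}")
            continue
        atom = _ATOM_ALIASES.get(atom_raw.strip().upper(), atom_raw.strip().upper())
        if atom in ("HA2", "HA3") and restype == "GLY":
            gly_ha.setdefault((chain, resnum, restype), []).append(value)
            continue
        if atom not in BACKBONE_NUCLEI:
            continue
        table.add(ShiftRecord(chain, resnum, restype, atom, value))
    for (chain, resnum, restype), vals in gly_ha.items():
        mean = sum(vals) / len(vals)
        table.add(ShiftRecord(chain, resnum, restype, "HA", mean))
    if len(table) == 0:
        raise EmptyShiftTableError("no backbone shifts found in input")
    return table


# ---------------------------------------------------------------------------
# NMR-STAR 3.1

def _star_tokens(text: str):
    """Tokenize a STAR file: whitespace-separated values, quoted strings,
    and semicolon-delimited multi-line values; comments stripped."""
    i, n = 0, len(text)
    at_line_start = True
    while i < n:
        ch = text[i]
        if ch in " \t":
            i += 1
            continue
        if ch in "\r\n":
            i += 1
            at_line_start = True
            continue
        if ch == "#":
            while i < n and text[i] not in "\r\n":
                i += 1
            continue
        if ch == ";" and at_line_start:
            j = text.find("\n;", i + 1)
            j = n if j < 0 else j
            yield text[i + 1:j]
            i = j + 2
            continue
        if ch in "'\"":
            j = text.find(ch, i + 1)
            j = n if j < 0 else j
            yield text[i + 1:j]
            i = j + 1
            at_line_start = False
            continue
        j = i
        while j < n and text[j] not in " \t\r\n":
            j += 1
        yield text[i:j]
        i = j
        at_line_start = False


def read_nmrstar(path: str | Path) -> ShiftTable:
    """Read backbone shifts from an NMR-STAR 3.1 assigned-chemical-shift loop.

    Only the value column is used; ambiguity codes and uncertainties are
    ignored.  Raises :class:`ShiftFormatError` if no such loop is present and
    :class:`EmptyShiftTableError` if the loop holds no backbone shifts.
    """
    text = Path(path).read_text()
    tokens = list(_star_tokens(text))
    rows: list[tuple[str, int, str, str, float]] = []
    found_loop = False
    i = 0
    while i < len(tokens):
        if tokens[i] != "loop_":
            i += 1
            continue
        i += 1
        tags = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        values = []
        while i < len(tokens) and tokens[i] != "stop_" and tokens[i] != "loop_" \
                and not tokens[i].startswith("_"):
            values.append(tokens[i])
            i += 1
        if not tags or not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        found_loop = True
        idx = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}

        def col(row, *names, default=None):
            for nm in names:
                if nm in idx and row[idx[nm]] not in (".", "?"):
                    return row[idx[nm]]
            return default

        ncol = len(tags)
        for r0 in range(0, len(values) - ncol + 1, ncol):
            row = values[r0:r0 + ncol]
            seq = col(row, "Seq_ID", "Comp_index_ID", "Auth_seq_ID")
            comp = col(row, "Comp_ID", "Auth_comp_ID")
            atom = col(row, "Atom_ID", "Auth_atom_ID")
            val = col(row, "Val", "Chem_shift_val")
            chain = col(row, "Auth_asym_ID", "Entity_assembly_ID", default="A")
            if None in (seq, comp, atom, val):
                continue
            try:
                rows.append((str(chain), int(seq), comp, atom, float(val)))
            except ValueError:
                continue
    if not found_loop:
        raise ShiftFormatError(
            f"{path}: no _Atom_chem_shift loop found (not NMR-STAR 3.1?)")
    return _build_table(rows)


# ---------------------------------------------------------------------------
# TSV

TSV_COLUMNS = ["chain", "residue_number", "residue_type", "atom", "shift_ppm"]


def read_shift_tsv(path: str | Path) -> ShiftTable:
    """Read backbone shifts from a headered tab/whitespace-separated table."""
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    except Exception as exc:
        raise ShiftFormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ShiftFormatError(f"{path}: missing columns {missing}")
    known = set(BACKBONE_NUCLEI) | set(_ATOM_ALIASES) | {"HA2", "HA3"}
    rows = []
    for rec in df.itertuples(index=False):
        atom = str(rec.atom).strip().upper()
        if atom not in known:
            warnings.warn(f"skipping unknown atom name {atom!r}")
            continue
        rows.append((str(rec.chain), int(rec.residue_number),
                     str(rec.residue_type), atom, float(rec.shift_ppm)))
    return _build_table(rows)


def write_shift_tsv(table: ShiftTable, path: str | Path) -> None:
    """Write a ShiftTable in the TSV dialect (full float precision)."""
    lines = ["\t".join(TSV_COLUMNS)]
    for key in sorted(table.records):
        r = table.records[key]
        lines.append(f"{r.chain_id}\t{r.residue_number}\t{r.residue_type}\t"
                     f"{r.nucleus}\t{r.shift_ppm!r}")
    Path(path).write_text("\n".join(lines) + "\n")
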
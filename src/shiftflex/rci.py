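"""Per-residue flexibility from backbone chemical shifts (random coil index).

The RCI of a residue is the inverse of a weighted average of its absolute
secondary chemical shifts,

    RCI = ( (A|dCA| + B|dCO| + C|dCB| + D|dN| + E|dNH| + F|dHA|)
            / (A + B + C + D + E + F) )^-1

where a secondary shift is the observed shift minus the sequence-corrected
random-coil shift.  The weighting coefficients are normalized (divided by
their sum) so that the baseline does not depend on which nuclei are
assigned; missing nuclei carry zero weight.  Secondary shifts are smoothed
with a 3-residue moving average before the weighted mean is formed, the raw
RCI is capped to [0, 0.2] (an entirely random-coil residue maps to the cap),
and finally rescaled onto [0, 1]:

    R' = min( max(RCI - 0.024, 0) / (0.2 - 0.024), 1 )

so that the modal RCI value 0.024 maps to zero and the flexible-terminus
cap 0.2 maps to one.  Residues without any assignment are treated as
entirely random-coil-like (secondary shifts of zero, so R' = 1) but are
masked out of downstream validation scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np

from .shifts import BACKBONE_NUCLEI, ShiftTable, expected_nuclei

RCI_CAP = 0.2
RCI_MODE = 0.024

_NUC_INDEX = {n: i for i, n in enumerate(BACKBONE_NUCLEI)}


class RCIConfigError(ValueError):
    """Random-coil or weight table does not cover the input."""


@dataclass
class RandomCoilTable:
    """Random-coil reference shifts plus nearest-neighbour corrections.

    ``shifts[restype][nucleus]`` is the random-coil value in ppm;
    ``neighbor[offset][neighbor_type][nucleus]`` (offset in -2..+2) is the
    additive correction applied when that neighbour type sits at the offset.
    """

    shifts: dict[str, dict[str, float]]
    neighbor: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    provenance: str = "unspecified"

    @classmethod
    def from_json(cls, path: str | Path) -> "RandomCoilTable":
        doc = json.loads(Path(path).read_text())
        neighbor = {int(k): v for k, v in doc.get("neighbor_corrections", {}).items()}
        return cls(shifts=doc["shifts"], neighbor=neighbor,
                   provenance=doc.get("provenance", "unspecified"))

    @classmethod
    def default(cls) -> "RandomCoilTable":
        with resources.as_file(
                resources.files("shiftflex.data") / "random_coil_synthetic.json") as p:
            return cls.from_json(p)

    def reference_shift(self, restype: str, nucleus: str,
                        neighbors: dict[int, str | None]) -> float:
        """Sequence-corrected random-coil shift for one residue/nucleus."""
        if restype not in self.shifts:
            raise RCIConfigError(f"residue type {restype!r} missing from "
                                 "random-coil table")
        base = self.shifts[restype].get(nucleus)
        if base is None:
            raise RCIConfigError(f"nucleus {nucleus} undefined for {restype}")
        corr = 0.0
        for off, ntype in neighbors.items():
            if ntype is None:
                continue
            corr += self.neighbor.get(off, {}).get(ntype, {}).get(nucleus, 0.0)
        return base + corr


@dataclass
class WeightTable:
    """Eq-style weighting coefficients for every nucleus combination.

    Coefficients for a combination default to the per-nucleus ``base``
    weights restricted to the assigned set; explicit per-combination
    overrides (keyed by a sorted ``+``-joined nucleus string, e.g.
    ``"C+CA+CB"``) take precedence.  All 63 non-empty combinations are
    therefore always covered.  ``unreliable`` lists combinations flagged as
    poor predictors (none are shipped by default).
    """

    base: dict[str, float]
    overrides: dict[frozenset, dict[str, float]] = field(default_factory=dict)
    unreliable: set[frozenset] = field(default_factory=set)
    provenance: str = "unspecified"

    @staticmethod
    def _key(combo) -> frozenset:
        return frozenset(combo)

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightTable":
        doc = json.loads(Path(path).read_text())
        overrides = {frozenset(k.split("+")): v
                     for k, v in doc.get("combinations", {}).items()}
        unreliable = {frozenset(k.split("+"))
                      for k in doc.get("unreliable_combinations", [])}
        return cls(base=doc["base"], overrides=overrides, unreliable=unreliable,
                   provenance=doc.get("provenance", "unspecified"))

    @classmethod
    def default(cls) -> "WeightTable":
        with resources.as_file(
                resources.files("shiftflex.data") / "weights_synthetic.json") as p:
            return cls.from_json(p)

    def weights_for(self, assigned: frozenset | set) -> np.ndarray:
        """Length-6 weight vector (order CA, CB, C, N, H, HA); zero for
        nuclei absent from the combination."""
        combo = frozenset(assigned)
        w = np.zeros(len(BACKBONE_NUCLEI))
        if not combo:
            return w
        src = self.overrides.get(combo, self.base)
        for nuc in combo:
            w[_NUC_INDEX[nuc]] = src.get(nuc, 0.0)
        return w

    def all_combinations(self) -> list[frozenset]:
        out = []
        for r in range(1, len(BACKBONE_NUCLEI) + 1):
            out.extend(frozenset(c) for c in combinations(BACKBONE_NUCLEI, r))
        return out


@dataclass
class FlexibilityProfile:
    """Per-residue flexibility in [0, 1] with a validity mask.

    ``source`` is ``"RCI"`` (shift-derived) or ``"RIGIDITY"``
    (structure-derived).  ``mask`` is False for residues excluded from
    validation scores (e.g. no shift assignments).
    """

    residue_numbers: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    source: str
    chain: str = "A"

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.residue_numbers) == len(self.values) == len(self.mask)):
            raise ValueError("profile arrays must have equal length")
        if np.any((self.values < -1e-12) | (self.values > 1 + 1e-12)):
            raise ValueError("profile values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def __len__(self) -> int:
        return len(self.values)


def secondary_shifts(table: ShiftTable, rc: RandomCoilTable,
                     sequence: list[tuple[str, int, str]] | None = None,
                     chain: str | None = None):
    """Absolute secondary shifts |observed - corrected random coil|.

    Returns ``(resnums, restypes, delta, assigned, residue_mask)`` where
    ``delta`` is an (n_residues, 6) array (order CA, CB, C, N, H, HA),
    ``assigned`` the matching boolean matrix and ``residue_mask`` is False
    for residues without any assignment (their deltas are zero: assumed
    entirely random-coil-like, excluded from scores downstream).
    """
    if sequence is None:
        sequence = table.residues(chain)
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    types = [t for _, _, t in sequence]
    delta = np.zeros((n, len(BACKBONE_NUCLEI)))
    assigned = np.zeros((n, len(BACKBONE_NUCLEI)), dtype=bool)
    residue_mask = np.zeros(n, dtype=bool)
    for i, (ch, num, restype) in enumerate(sequence):
        neighbors = {off: (types[i + off] if 0 <= i + off < n else None)
                     for off in (-2, -1, 1, 2)}
        for k, nuc in enumerate(BACKBONE_NUCLEI):
            obs = table.get(ch, num, nuc)
            if obs is None:
                continue
            ref = rc.reference_shift(restype, nuc, neighbors)
            delta[i, k] = abs(obs - ref)
            assigned[i, k] = True
        residue_mask[i] = assigned[i].any()
    return (np.array([num for _, num, _ in sequence]), types,
            delta, assigned, residue_mask)


def smooth3(values: np.ndarray) -> np.ndarray:
    """Centered 3-residue moving average; windows truncate at the termini."""
    v = np.asarray(values, dtype=float)
    if v.shape[0] == 0:
        return v.copy()
    padded_sum = np.zeros_like(v)
    count = np.zeros(v.shape[0])
    for off in (-1, 0, 1):
        lo, hi = max(0, -off), v.shape[0] - max(0, off)
        padded_sum[lo:hi] += v[lo + off:hi + off]
        count[lo:hi] += 1
    if v.ndim > 1:
        count = count.reshape(-1, *([1] * (v.ndim - 1)))
    return padded_sum / count


def rci(delta_smoothed: np.ndarray, assigned: np.ndarray,
        weights: WeightTable) -> np.ndarray:
    """Raw RCI per residue: inverse normalized weighted mean of |ddelta|,
    capped to [0, 0.2]; an all-zero weighted mean maps to the cap."""
    delta_smoothed = np.asarray(delta_smoothed, dtype=float)
    n = delta_smoothed.shape[0]
    out = np.empty(n)
    for i in range(n):
        combo = frozenset(nuc for k, nuc in enumerate(BACKBONE_NUCLEI)
                          if assigned[i, k])
        w = weights.weights_for(combo)
        wsum = w.sum()
        if combo and wsum <= 0:
            raise RCIConfigError(
                f"all-zero weights for combination {sorted(combo)}")
        mean = float(w @ delta_smoothed[i] / wsum) if wsum > 0 else 0.0
        out[i] = RCI_CAP if mean <= 1.0 / RCI_CAP else 1.0 / mean
    return np.clip(out, 0.0, RCI_CAP)


def rescale_rci(raw: np.ndarray) -> np.ndarray:
    """Rescale raw RCI onto [0, 1]: (RCI - 0.024)/(0.2 - 0.024), clamped."""
    raw = np.asarray(raw, dtype=float)
    return np.minimum(np.maximum(raw - RCI_MODE, 0.0) / (RCI_CAP - RCI_MODE), 1.0)


def rci_profile(table: ShiftTable, rc: RandomCoilTable | None = None,
                weights: WeightTable | None = None,
                sequence: list[tuple[str, int, str]] | None = None,
                chain: str | None = None) -> FlexibilityProfile:
    """Full shift-to-flexibility pipeline for one chain."""
    rc = rc or RandomCoilTable.default()
    weights = weights or WeightTable.default()
    resnums, _, delta, assigned, mask = secondary_shifts(
        table, rc, sequence=sequence, chain=chain)
    smoothed = smooth3(delta)
    raw = rci(smoothed, assigned, weights)
    chain_id = chain or (sequence[0][0] if sequence else table.chains[0])
    return FlexibilityProfile(resnums, rescale_rci(raw), mask,
                              source="RCI", chain=chain_id)
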
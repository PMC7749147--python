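"""High-level interface: a validation model built from data and a results
object carrying scores, profiles and diagnostics.

:class:`StructureValidation` pairs a coordinate ensemble with a backbone
shift table; :meth:`StructureValidation.fit` runs the full pipeline —
residue mapping, RCI, constraint network, hydrogen-bond dilution,
Boltzmann conversion and scoring — and returns a
:class:`StructureValidationResults` with per-model profiles, raw and
percentile scores, a text summary and output writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rci as _rci
from .network import HB_DEFAULT_CUTOFF, build_graph
from .rigidity import (DEFAULT_TEMPERATURE, RIGID_CLUSTER_MIN_ATOMS,
                       boltzmann_flex, dilution)
from .rci import FlexibilityProfile, RandomCoilTable, WeightTable
from .scoring import ReferenceDistribution, ScoreReport, score_ensemble
from .shifts import ShiftTable, completeness, read_nmrstar, read_shift_tsv
from .structure import Model, ensure_protons, map_residues, read_models


class StructureValidation:
    """Validate an NMR ensemble (or single model) against backbone shifts.

    Parameters
    ----------
    models : list of Model
        Normalized coordinate models (see :func:`shiftflex.read_models`).
    shift_table : ShiftTable
        Backbone chemical-shift assignments.
    chain : str, optional
        Chain to validate; defaults to the first protein chain.
    reference : ReferenceDistribution, optional
        Reference raw-score distributions for percentile scoring.
    proton_mode : {"require", "minimal-amide"}
        How to handle missing amide protons.
    include_cutoff : float
        Hydrogen-bond inclusion cutoff in kcal/mol.
    temperature : float
        Temperature for the Boltzmann conversion, in kelvin.
    """

    def __init__(self, models: list[Model], shift_table: ShiftTable,
                 chain: str | None = None,
                 reference: ReferenceDistribution | None = None,
                 random_coil: RandomCoilTable | None = None,
                 weights: WeightTable | None = None,
                 proton_mode: str = "require",
                 include_cutoff: float = HB_DEFAULT_CUTOFF,
                 temperature: float = DEFAULT_TEMPERATURE,
                 min_cluster_atoms: int = RIGID_CLUSTER_MIN_ATOMS):
        if not models:
            raise ValueError("need at least one model")
        self.models = models
        self.shift_table = shift_table
        self.chain = chain or models[0].chains[0]
        self.reference = reference or ReferenceDistribution.default()
        self.random_coil = random_coil or RandomCoilTable.default()
        self.weights = weights or WeightTable.default()
        self.proton_mode = proton_mode
        self.include_cutoff = include_cutoff
        self.temperature = temperature
        self.min_cluster_atoms = min_cluster_atoms

    @classmethod
    def from_files(cls, structure_path: str | Path, shifts_path: str | Path,
                   model_indices: list[int] | None = None,
                   **kwargs) -> "StructureValidation":
        """Build from a PDB/mmCIF file and an NMR-STAR or TSV shift file."""
        models = read_models(structure_path)
        if model_indices is not None:
            models = [models[i] for i in model_indices]
        text_head = Path(shifts_path).read_text()[:4096]
        if "_Atom_chem_shift" in text_head or "save_" in text_head \
                or "data_" in text_head:
            table = read_nmrstar(shifts_path)
        else:
            table = read_shift_tsv(shifts_path)
        return cls(models, table, **kwargs)

    def fit(self) -> "StructureValidationResults":
        """Run the full validation pipeline."""
        profile_pairs = []
        per_model_rows = []
        dilutions = []
        for model in self.models:
            prepared = ensure_protons(model, mode=self.proton_mode)
            rmap = map_residues(prepared, self.shift_table, chain=self.chain)
            rids = prepared.chain_residues(self.chain)
            shift_of = dict(rmap.pairs)

            # RCI over the structure's residue ordering, so both profiles
            # share indexing; unmapped residues are masked out.
            sequence = []
            for rid in rids:
                sres = shift_of.get(rid)
                sc, sn = sres if sres else (self.chain, rid[1])
                sequence.append((sc, sn, prepared.residue_type(rid)))
            rci_prof = _rci.rci_profile(self.shift_table, self.random_coil,
                                        self.weights, sequence=sequence,
                                        chain=self.chain)
            unmapped = np.array([rid not in shift_of for rid in rids])
            rci_prof.mask &= ~unmapped

            graph = build_graph(prepared, include_cutoff=self.include_cutoff)
            dil = dilution(graph, include_cutoff=self.include_cutoff,
                           min_atoms=self.min_cluster_atoms)
            rig_full = boltzmann_flex(dil, temperature=self.temperature)
            keep = [k for k, rid in enumerate(graph.residue_ids)
                    if rid in set(rids)]
            rig_prof = FlexibilityProfile(
                rig_full.residue_numbers[keep], rig_full.values[keep],
                rig_full.mask[keep], source="RIGIDITY", chain=self.chain)
            rci_prof = FlexibilityProfile(
                np.array([rid[1] for rid in rids]), rci_prof.values,
                rci_prof.mask, source="RCI", chain=self.chain)
            profile_pairs.append((rci_prof, rig_prof))
            dilutions.append(dil)
            for k, rid in enumerate(rids):
                per_model_rows.append(
                    (model.index, self.chain, rid[1], rid[2],
                     prepared.residue_type(rid), rci_prof.values[k],
                     rig_prof.values[k], bool(rci_prof.mask[k])))

        comp = completeness(
            self.shift_table,
            sequence=[(c, n, t) for (c, n, t) in
                      [(self.chain, rid[1], self.models[0].residue_type(rid))
                       for rid in self.models[0].chain_residues(self.chain)]])
        report = score_ensemble(profile_pairs, ref=self.reference,
                                completeness=comp)
        profiles = pd.DataFrame(
            per_model_rows,
            columns=["model", "chain", "residue_number", "insertion_code",
                     "residue_type", "rci", "rigidity", "scored"])
        return StructureValidationResults(model=self, report=report,
                                          profiles=profiles,
                                          profile_pairs=profile_pairs,
                                          dilutions=dilutions)


@dataclass
class StructureValidationResults:
    """Fitted validation results.

    Attributes
    ----------
    report : ScoreReport
        Raw Spearman/RMSD values and percentile scores per model plus
        ensemble means.
    profiles : pandas.DataFrame
        Long-format per-residue table (model, residue, rescaled RCI,
        rigidity probability, scored flag).
    """

    model: StructureValidation
    report: ScoreReport
    profiles: pd.DataFrame
    profile_pairs: list = field(default_factory=list, repr=False)
    dilutions: list = field(default_factory=list, repr=False)

    def summary(self) -> str:
        """Human-readable summary table."""
        rep = self.report
        lines = []
        lines.append("Structure validation against backbone chemical shifts")
        lines.append("=" * 60)
        lines.append(f"chain: {self.model.chain}    models: {len(rep.models)}"
                     f"    residues scored: {rep.models[0].n_residues}")
        lines.append(f"shift completeness: {rep.completeness:.1%}"
                     + ("   [flagged: below 75%, scores less reliable]"
                        if rep.low_completeness else ""))
        lines.append(f"reference set: {rep.reference}")
        lines.append("-" * 60)
        lines.append(f"{'model':>5} {'rho':>8} {'corr score':>11} "
                     f"{'rmsd':>8} {'rmsd score':>11}")
        for m in rep.models:
            rho = "   n/a" if m.spearman_rho is None else f"{m.spearman_rho:8.3f}"
            cs = "    n/a" if m.correlation_score is None \
                else f"{m.correlation_score:11.1f}"
            lines.append(f"{m.model_index:>5} {rho} {cs} "
                         f"{m.rmsd:8.3f} {m.rmsd_score:11.1f}")
        lines.append("-" * 60)
        rho = rep.mean_spearman
        cs = rep.mean_correlation_score
        lines.append(
            f"{'mean':>5} {rho if rho is None else format(rho, '8.3f')} "
            f"{cs if cs is None else format(cs, '11.1f')} "
            f"{rep.mean_rmsd:8.3f} {rep.mean_rmsd_score:11.1f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> list[Path]:
        """Write per-residue TSVs (one per model) and the JSON report."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for model_index, sub in self.profiles.groupby("model"):
            path = out_dir / f"profile_model{model_index}.tsv"
            sub.to_csv(path, sep="\t", index=False)
            written.append(path)
        report_path = out_dir / "scores.json"
        self.report.to_json(report_path)
        written.append(report_path)
        return written

    def plot_profile(self, model_index: int = 0, ax=None):
        """Plot the two flexibility profiles for one model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        rci_prof, rig_prof = self.profile_pairs[model_index]
        ax.plot(rci_prof.residue_numbers, rci_prof.values,
                label="RCI (shifts)", color="tab:blue")
        ax.plot(rig_prof.residue_numbers, rig_prof.values,
                label="rigidity (structure)", color="tab:orange")
        ax.set_xlabel("residue")
        ax.set_ylabel("flexibility")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(loc="upper center", ncol=2)
        return ax
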
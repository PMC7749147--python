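# Methods

## The validation problem

Solution NMR structures lack an analogue of the crystallographic *R*
factor: the deposited restraints are heavily curated, so comparing a
structure back to them says little about accuracy. Backbone chemical
shifts, by contrast, are measured early, reliably and with minimal
manipulation, and they encode local backbone rigidity. shiftflex therefore
validates a structure by asking whether the flexibility implied by its
geometry matches the flexibility implied by the shifts.

Two per-residue flexibility profiles on [0, 1] are computed and compared:

1. **Shift-derived (rescaled RCI).** The random coil index of residue *i*
   is the inverse of a normalized weighted mean of absolute secondary
   shifts,

       RCI_i = ( Σ_k w_k |Δδ_{i,k}| / Σ_k w_k )⁻¹ ,

   where *k* runs over the assigned backbone nuclei (Cα, Cβ, C′, N, HN,
   Hα), Δδ is observed minus sequence-corrected random-coil shift, and
   missing nuclei carry zero weight. Normalizing by Σw keeps the baseline
   comparable across the 63 possible nucleus combinations. Secondary
   shifts are smoothed with a centered 3-residue moving average (windows
   truncate at the termini; zero-padding would fabricate terminal
   rigidity) before the weighted mean is formed. The raw value is capped
   to [0, 0.2] — a fully random-coil residue maps to the cap — and
   rescaled by

       R′ = min( max(RCI − 0.024, 0) / (0.2 − 0.024), 1 ),

   which sends the modal raw value 0.024 to 0 and the flexible-terminus
   cap 0.2 to 1. Residues with no assignments at all are treated as
   entirely random-coil-like (R′ = 1) but masked out of the scores.

2. **Structure-derived (body-bar rigidity).** Each atom is a rigid body
   with six degrees of freedom. Constraints are multi-edges ("bars"):
   5 for a rotatable single covalent bond, 6 for double/partial-double/
   delocalized bonds (peptide bonds, carboxylates, amides, guanidinium,
   aromatic rings — their dihedral is locked), 5 for a hydrogen bond
   retained at the current energy cutoff, 2 for a hydrophobic tether
   (C/S atoms with only C/S/H neighbours, within the van der Waals sum
   + 0.25 Å, at least 3 covalent bonds apart). Hydrogen-bond energies use
   a Mayo-type potential E = V₀(5(d₀/d)¹² − 6(d₀/d)¹⁰)·F with V₀ = 8
   kcal/mol, d₀ = 2.8 Å, d the donor–acceptor distance, and
   F = cos²θ·exp(−(π−θ)⁶)·cos²(φ−φ₀) built from the donor–H–acceptor
   angle θ and the H–acceptor–base angle φ (φ₀ = 120° for sp² acceptors,
   109.5° for sp³). Only the *ordering* of energies matters downstream,
   so the functional form is isolated behind `hbond_energy` and can be
   swapped. Protonated nitrogens are not acceptors.

   The (6,6) pebble game decides constraint independence (a bar is
   independent iff 7 pebbles can be gathered on its endpoints), which by
   Tay's theorem computes exact generic body-bar rigidity. Rigid clusters
   are the classes of the mutual-rigidity relation, found by pairwise
   pebble tests over adjacent vertices plus union–find; a residue is rigid
   iff its Cα belongs to a cluster of ≥ 15 atoms (smaller covalently rigid
   units — proline and aromatic rings — must not count). Hydrogen-bond
   dilution removes bonds weakest to strongest (distinct energies; exact
   ties leave together), recomputing the decomposition at each cutoff from
   scratch, and records the first cutoff E_c at which each residue stops
   being rigid. Residues never rigid map to probability 1; residues still
   rigid with zero hydrogen bonds map to 0; residues that only lose
   rigidity when the strongest bonds vanish are assigned the strongest
   bond's energy. Otherwise the flexibility probability is the Boltzmann
   factor p = exp(E_c / RT) at T = 298.15 K (R = 0.0019872
   kcal mol⁻¹ K⁻¹), clamped to [0, 1].

## Scores

Per model, the two profiles are compared over residues unmasked on both
sides: a Spearman rank correlation (are rigid/flexible regions — i.e.
secondary structure — in the right places?) and

    RMSD = sqrt( Σ_i (R′_RCI,i − R_rigidity,i)² / N )

(is the structure overall too rigid or too floppy?). Raw values are
converted to percentiles against a reference distribution, oriented so
higher is always better (RMSD percentile counts reference values *above*
the raw value), with ties contributing half their count. Ensemble scores
are unweighted means over models. The two scores measure different
failure modes and are deliberately not combined into one number.
Completeness below 75% of the expected backbone shifts (per-residue
expected sets: {Cα, Cβ, C′, N, HN, Hα} minus Cβ for Gly, minus HN for
Pro; the first residue's N/HN are excluded from the denominator) flags
the result as less reliable.

The shipped reference (`data/reference_synthetic.json`) is built from
this package's own fixture ensembles and is labelled as such; percentile
scores are only comparable under the same reference. `shiftflex reference
build` assembles a reference from any directory of prior score reports.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| H-bond inclusion cutoff | −0.01 | kcal/mol | weaker contacts ignored |
| V₀, d₀ (Mayo) | 8, 2.8 | kcal/mol, Å | ordering-only role |
| hydrophobic slack | 0.25 | Å | added to vdW radii sum |
| rigid-cluster threshold | 15 | atoms | Cα cluster size for "rigid" |
| temperature | 298.15 | K | Boltzmann conversion |
| raw RCI cap / mode | 0.2 / 0.024 | RCI units | rescaling fixed points |
| completeness flag | 0.75 | fraction | "less reliable" threshold |

## Synthetic data

`fixtures` generates poly-alanine models (N, CA, C, O, CB + amide H) from
internal coordinates: α-helix (φ/ψ = −57°/−47°), a β-hairpin whose
strand/turn torsions were tuned numerically so the rigid ideal-geometry
chain actually closes its cross-strand hydrogen-bond ladder, a
seed-randomized coil, and a two-helix construct with a flexible linker.
A seeded isotropic coordinate perturbation (default 0.05 Å) is applied:
perfectly regular geometry makes all helix hydrogen bonds *exactly*
degenerate in energy, a situation real coordinates never produce, and the
perturbation restores the realistic feature that dilution resolves a
gradient of transition energies. All generators are byte-deterministic
given a seed.

`make_shifts` inverts the RCI pipeline for a chosen target profile: the
rescaling and the inverse weighted mean are applied analytically, the
3-residue smoothing is undone with a least-squares solve (the smoothing
operator is singular when n ≡ 2 mod 3), and the required secondary-shift
magnitude is split across nuclei with per-nucleus scales chosen so proton
shifts stay inside physical ranges; magnitudes are clamped where sharp
target steps would demand unphysical shifts, so the round trip is exact
for smooth targets and degrades only at steps. What passing round-trip
tests show is that the pipeline algebra is self-consistent — not that the
synthetic shifts resemble measured chemical-shift physics: the magnitudes
at the rigid extreme are deliberately exaggerated, residue chemistry is
uniform poly-Ala, and no shift-referencing errors, peak overlap or
assignment mistakes are emulated.

The shipped random-coil and weight tables are synthetic stand-ins with
plausible magnitudes (carbons weighted most, protons least); production
use should substitute measured IDP-derived random-coil values and
optimized per-combination coefficients via the JSON loaders.

## Numerical choices

* Pebble searches are depth-first with lowest-vertex tie-breaking, so runs
  are deterministic; independence flags depend on insertion order but DOF
  and clusters do not (matroid property, tested).
* Dilution recomputes the decomposition per cutoff (the literal
  procedure); with ~10² atoms and ~10¹ distinct energies this costs well
  under a second per model.
* The brute-force oracle computes the generic rank two independent ways —
  exhaustive (6,6)-subset counting and Gaussian elimination of a random
  Plücker-coordinate rigidity matrix over GF(2³¹−1), avoiding any
  floating-point rank tolerance — and refuses graphs above 12 vertices.
* Degenerate amide geometry (colinear C(i−1)–N–CA) falls back to an
  arbitrary perpendicular H direction; hydrogen-bond θ ≤ 90° scores zero.
* Altloc groups keep the first-listed conformer; insertion codes are part
  of the residue identity; MSE and similar standard-parent residues are
  remapped to their parent without coordinate changes.
* Test problem sizes: 1000 random multigraphs (≤ 10 vertices, ≤ 40 bars)
  for the oracle equivalence, 20-residue helix and 16-residue hairpin for
  the end-to-end and dilution checks — sizes at which the exhaustive
  oracle is exact and the full suite runs in seconds.

## Known limitations

* No loop rebuilding or full protonation: structures lacking more than
  amide protons must be protonated externally; `minimal-amide` mode only
  places backbone HN.
* Ligands, nucleic acids and metal coordination are not modelled; waters
  and non-protein heteroatoms are dropped.
* Shift re-referencing errors are read verbatim (no correction applied).
* Percentile scores depend entirely on the reference distribution; the
  shipped synthetic reference makes scores self-consistent within this
  package but not comparable to scores computed against survey-scale
  references.
* The 5-bar hydrogen-bond convention is fixed; 1–3 bar variants are out
  of scope.
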
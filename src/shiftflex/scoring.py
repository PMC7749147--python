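"""Agreement between shift-derived and structure-derived flexibility.

Two complementary measures per model: the Spearman rank correlation of the
two profiles (are peaks and troughs — i.e. secondary structure — in the
right places?) and their root-mean-square deviation

    RMSD = sqrt( sum (R'_RCI - R_rigidity)^2 / N )

(is the structure overall too rigid or too floppy?).  Raw values are
converted to percentile scores against a reference distribution so that
higher is always better; per-ensemble scores are unweighted means over
models.  Residues masked in either profile (typically: no shift
assignments) are excluded from N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .rci import FlexibilityProfile


class ConstantProfileError(ValueError):
    """Spearman correlation undefined: one profile is constant."""


@dataclass
class ReferenceDistribution:
    """Sorted raw correlation and RMSD values used for percentile scoring."""

    correlation: np.ndarray
    rmsd: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self):
        self.correlation = np.sort(np.asarray(self.correlation, dtype=float))
        self.rmsd = np.sort(np.asarray(self.rmsd, dtype=float))
        if len(self.correlation) == 0 or len(self.rmsd) == 0:
            raise ValueError("reference distributions must be non-empty")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDistribution":
        doc = json.loads(Path(path).read_text())
        return cls(correlation=doc["correlation"], rmsd=doc["rmsd"],
                   provenance=doc.get("provenance", "unspecified"))

    def to_json(self, path: str | Path) -> None:
        doc = {"provenance": self.provenance,
               "correlation": self.correlation.tolist(),
               "rmsd": self.rmsd.tolist()}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def default(cls) -> "ReferenceDistribution":
        with resources.as_file(
                resources.files("shiftflex.data") / "reference_synthetic.json") as p:
            return cls.from_json(p)


def _common(a: FlexibilityProfile, b: FlexibilityProfile, mask=None):
    if len(a) != len(b):
        raise ValueError("profiles have different lengths")
    m = a.mask & b.mask
    if mask is not None:
        m = m & np.asarray(mask, dtype=bool)
    return a.values[m], b.values[m]


def spearman(a: FlexibilityProfile, b: FlexibilityProfile, mask=None) -> float:
    """Spearman rho over unmasked residues (average ranks for ties)."""
    x, y = _common(a, b, mask)
    if len(x) < 3:
        raise ValueError("need at least 3 unmasked residues")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("constant profile: correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def rmsd(a: FlexibilityProfile, b: FlexibilityProfile, mask=None) -> float:
    """Root-mean-square deviation between profiles over unmasked residues."""
    x, y = _common(a, b, mask)
    if len(x) == 0:
        raise ValueError("no unmasked residues")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def percentile_score(raw: float, ref: ReferenceDistribution,
                     metric: str) -> float:
    """Percentile of ``raw`` in the reference set, oriented so that higher
    scores are better; ties contribute half their count (midpoint rule)."""
    if metric == "correlation":
        values = ref.correlation
        below = np.count_nonzero(values < raw)
    elif metric == "rmsd":
        values = ref.rmsd
        below = np.count_nonzero(values > raw)  # lower RMSD is better
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ties = np.count_nonzero(values == raw)
    return 100.0 * (below + 0.5 * ties) / len(values)


@dataclass
class ModelScore:
    """Raw and percentile scores for one model (or one chain)."""

    model_index: int
    spearman_rho: float | None
    rmsd: float
    correlation_score: float | None
    rmsd_score: float
    n_residues: int
    note: str = ""


@dataclass
class ScoreReport:
    """Per-model scores plus ensemble means and provenance."""

    models: list[ModelScore]
    reference: str
    completeness: float | None = None

    @property
    def mean_spearman(self) -> float | None:
        vals = [m.spearman_rho for m in self.models if m.spearman_rho is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_rmsd(self) -> float:
        return float(np.mean([m.rmsd for m in self.models]))

    @property
    def mean_correlation_score(self) -> float | None:
        vals = [m.correlation_score for m in self.models
                if m.correlation_score is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_rmsd_score(self) -> float:
        return float(np.mean([m.rmsd_score for m in self.models]))

    @property
    def low_completeness(self) -> bool:
        """Shift completeness below 75%: scores flagged as less reliable."""
        return self.completeness is not None and self.completeness < 0.75

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "completeness": self.completeness,
            "low_completeness_flag": self.low_completeness,
            "ensemble": {
                "spearman_rho": self.mean_spearman,
                "rmsd": self.mean_rmsd,
                "correlation_score": self.mean_correlation_score,
                "rmsd_score": self.mean_rmsd_score,
            },
            "models": [
                {"model": m.model_index, "spearman_rho": m.spearman_rho,
                 "rmsd": m.rmsd, "correlation_score": m.correlation_score,
                 "rmsd_score": m.rmsd_score, "n_residues": m.n_residues,
                 "note": m.note}
                for m in self.models
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True))


def score_model(rci_prof: FlexibilityProfile, rig_prof: FlexibilityProfile,
                ref: ReferenceDistribution, model_index: int = 0) -> ModelScore:
    """Score one (RCI, rigidity) profile pair against the reference."""
    n = int(np.count_nonzero(rci_prof.mask & rig_prof.mask))
    r = rmsd(rci_prof, rig_prof)
    note = ""
    try:
        rho = spearman(rci_prof, rig_prof)
        corr_score = percentile_score(rho, ref, "correlation")
    except ConstantProfileError:
        rho, corr_score = None, None
        note = "constant profile: correlation undefined, RMSD only"
    return ModelScore(model_index=model_index, spearman_rho=rho, rmsd=r,
                      correlation_score=corr_score,
                      rmsd_score=percentile_score(r, ref, "rmsd"),
                      n_residues=n, note=note)


def score_ensemble(profile_pairs, ref: ReferenceDistribution | None = None,
                   completeness: float | None = None) -> ScoreReport:
    """Score a sequence of (RCI profile, rigidity profile) pairs."""
    ref = ref or ReferenceDistribution.default()
    pairs = list(profile_pairs)
    if not pairs:
        raise ValueError("need at least one model")
    models = [score_model(a, b, ref, model_index=i)
              for i, (a, b) in enumerate(pairs)]
    return ScoreReport(models=models, reference=ref.provenance,
                       completeness=completeness)
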
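"""Species-by-habitat impact weights under uncertainty-averse aggregation.

Each documented impact of a species on a habitat type carries an impact
*magnitude* class (an ordered vocabulary, low to high, after the EICAT
scheme) and an *evidence strength* class (weak to strong). A weight
matrix maps each (magnitude, evidence) pair to a non-negative numeric
weight; when several impacts are documented for one species-habitat
pair the uncertainty-averse rule applies: the worst documented impact
(maximum weight) governs.

Vocabularies and the numeric grid ship as configuration, not code — the
engine only enforces ordinality, non-negativity, and monotonicity of
weight in magnitude at fixed evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EvidenceEntry:
    """One documented impact of a species on a habitat type."""

    species_id: str
    habitat_id: str
    magnitude: str
    evidence: str


@dataclass
class WeightMatrix:
    """Numeric weights over ordered (magnitude x evidence) classes."""

    magnitude_classes: list[str]  # ordered low -> high
    evidence_classes: list[str]  # ordered weak -> strong
    weights: np.ndarray  # shape (n_magnitude, n_evidence)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.magnitude_classes), len(self.evidence_classes)):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{len(self.magnitude_classes)} magnitude x "
                f"{len(self.evidence_classes)} evidence classes"
            )

    def weight_of(self, magnitude: str, evidence: str) -> float:
        try:
            i = self.magnitude_classes.index(magnitude)
        except ValueError:
            raise KeyError(f"unknown magnitude class {magnitude!r}") from None
        try:
            j = self.evidence_classes.index(evidence)
        except ValueError:
            raise KeyError(f"unknown evidence class {evidence!r}") from None
        return float(self.weights[i, j])

    @property
    def top_magnitude(self) -> str:
        return self.magnitude_classes[-1]

    def to_config(self) -> dict:
        return {
            "magnitude_classes": list(self.magnitude_classes),
            "evidence_classes": list(self.evidence_classes),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "WeightMatrix":
        return cls(
            magnitude_classes=list(cfg["magnitude_classes"]),
            evidence_classes=list(cfg["evidence_classes"]),
            weights=np.asarray(cfg["weights"], dtype=float),
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_matrix(matrix: WeightMatrix) -> ValidationReport:
    """Report non-negativity violations (errors) and non-monotonicity
    of weight in magnitude at fixed evidence (warnings)."""
    report = ValidationReport()
    neg = np.argwhere(matrix.weights < 0)
    for i, j in neg:
        report.errors.append(
            f"negative weight {matrix.weights[i, j]} at "
            f"(magnitude={matrix.magnitude_classes[i]}, "
            f"evidence={matrix.evidence_classes[j]})"
        )
    diffs = np.diff(matrix.weights, axis=0)
    for i, j in np.argwhere(diffs < 0):
        report.warnings.append(
            "weight decreases with magnitude at fixed evidence "
            f"({matrix.magnitude_classes[i]} -> {matrix.magnitude_classes[i + 1]} "
            f"at evidence={matrix.evidence_classes[j]})"
        )
    return report


@dataclass
class ImpactWeightTable:
    """Resolved weights w_ij; absent pairs mean zero weight."""

    w: dict[tuple[str, str], float]

    def get(self, species_id: str, habitat_id: str) -> float:
        return self.w.get((species_id, habitat_id), 0.0)

    def species(self) -> set[str]:
        return {s for s, _ in self.w}

    def habitats(self) -> set[str]:
        return {h for _, h in self.w}

    def scaled(self, c: float) -> "ImpactWeightTable":
        return ImpactWeightTable({k: c * v for k, v in self.w.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": s, "habitat": h, "weight": v}
            for (s, h), v in sorted(self.w.items())
        ]
        return pd.DataFrame(rows, columns=["species", "habitat", "weight"])


def resolve_weights(
    entries: Iterable[EvidenceEntry], matrix: WeightMatrix
) -> ImpactWeightTable:
    """Aggregate documented impacts into per-(species, habitat) weights.

    The uncertainty-averse rule: w_ij is the maximum matrix weight over
    all documented impacts of species i on habitat j. Pairs with no
    documented impact are absent (implicit zero). Unknown class tokens
    raise, naming the offending entry.
    """
    report = validate_matrix(matrix)
    if not report.ok:
        raise ValueError("invalid weight matrix: " + "; ".join(report.errors))
    w: dict[tuple[str, str], float] = {}
    for e in entries:
        try:
            value = matrix.weight_of(e.magnitude, e.evidence)
        except KeyError as err:
            raise KeyError(f"{err.args[0]} in entry {e}") from None
        key = (e.species_id, e.habitat_id)
        w[key] = max(w.get(key, 0.0), value)
    return ImpactWeightTable(w)


def entries_from_frame(df: pd.DataFrame) -> list[EvidenceEntry]:
    """Build evidence entries from a table with columns
    species, habitat, magnitude, evidence."""
    needed = ["species", "habitat", "magnitude", "evidence"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table missing columns {missing}")
    return [
        EvidenceEntry(r.species, r.habitat, r.magnitude, r.evidence)
        for r in df.itertuples(index=False)
    ]
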
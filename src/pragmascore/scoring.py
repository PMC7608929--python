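"""Subscore computation for the two CT scoring systems.

PRAGMA-CF subscores are volume fractions: the share of lung grid cells
(pooled over the 10 axial slices, every lung cell weighted equally)
carrying each hierarchical label, expressed as % of total lung volume.
The composite %Disease is %Bronchiectasis + %Mucus Plugging + %AWT.

CF-CT subscores are percent-of-maximum scores.  Each of the 6 regions is
graded 0-3 per component and a per-component multiplier is applied; with
the default multipliers (bronchiectasis 4, AWT 3, mucus plugging 2,
parenchyma 3) the component maxima over 6 regions are 72, 54, 36 and 54,
and the maximal total is 216.  The CF-CT composite %Disease is the summed
airway raw score as a percentage of its summed maximum (162 by default):
the literal sum of three percent-of-maximum values is not a percentage of
anything and does not match how composite CF-CT scores are tabulated.

Scores travel in a tidy table with columns
``patient_id, visit, system, subscore, value`` (system ``pragma``/``cfct``).
Values are carried at full floating precision; rounding happens only in
report rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    COMPONENTS,
    REGIONS,
    CellLabel,
    GridAnnotation,
    LobeAssessmentSet,
)

__all__ = [
    "PragmaScores",
    "CfctScores",
    "DeltaRecord",
    "DEFAULT_CFCT_WEIGHTS",
    "CFCT_COMPONENT_MAXIMA",
    "CFCT_TOTAL_MAX",
    "pragma_subscores",
    "cfct_scores",
    "compute_deltas",
    "scores_to_frame",
    "read_scores",
    "write_scores",
]

MAX_EXTENT_CODE = 3

#: Per-component multipliers applied to the 0-3 extent codes.  Chosen so
#: that 6 regions x multiplier x 3 reproduces the published component
#: maxima (72/54/36/54); a different rubric can be plugged in via the
#: ``weights`` argument of :func:`cfct_scores`.
DEFAULT_CFCT_WEIGHTS: dict[str, int] = {
    "bronchiectasis": 4,
    "awt": 3,
    "mucus_plugging": 2,
    "parenchyma": 3,
}

CFCT_COMPONENT_MAXIMA = {
    c: len(REGIONS) * MAX_EXTENT_CODE * k for c, k in DEFAULT_CFCT_WEIGHTS.items()
}
CFCT_TOTAL_MAX = sum(CFCT_COMPONENT_MAXIMA.values())  # 216
#: Airway components entering the %Disease composite.
DISEASE_COMPONENTS = ("bronchiectasis", "awt", "mucus_plugging")

PRAGMA_SUBSCORES = (
    "bronchiectasis",
    "mucus_plugging",
    "awt",
    "atelectasis",
    "normal",
    "disease",
)
CFCT_SUBSCORES = ("bronchiectasis", "awt", "mucus_plugging", "parenchyma", "total", "disease")


@dataclass(frozen=True)
class PragmaScores:
    """PRAGMA-CF subscores, each a percent of total lung volume."""

    pct_bronchiectasis: float
    pct_mucus_plugging: float
    pct_awt: float
    pct_atelectasis: float
    pct_normal: float

    @property
    def pct_disease(self) -> float:
        return self.pct_bronchiectasis + self.pct_mucus_plugging + self.pct_awt

    def as_dict(self) -> dict[str, float]:
        return {
            "bronchiectasis": self.pct_bronchiectasis,
            "mucus_plugging": self.pct_mucus_plugging,
            "awt": self.pct_awt,
            "atelectasis": self.pct_atelectasis,
            "normal": self.pct_normal,
            "disease": self.pct_disease,
        }


@dataclass(frozen=True)
class CfctScores:
    """CF-CT raw and percent-of-maximum subscores."""

    raw: Mapping[str, int]
    maxima: Mapping[str, int]

    @property
    def raw_total(self) -> int:
        return int(sum(self.raw.values()))

    @property
    def pct(self) -> dict[str, float]:
        return {c: 100.0 * self.raw[c] / self.maxima[c] for c in self.raw}

    @property
    def pct_total(self) -> float:
        return 100.0 * self.raw_total / sum(self.maxima.values())

    @property
    def pct_disease(self) -> float:
        num = sum(self.raw[c] for c in DISEASE_COMPONENTS)
        den = sum(self.maxima[c] for c in DISEASE_COMPONENTS)
        return 100.0 * num / den

    def as_dict(self) -> dict[str, float]:
        out = dict(self.pct)
        out["total"] = self.pct_total
        out["disease"] = self.pct_disease
        return out


@dataclass(frozen=True)
class DeltaRecord:
    """EOS minus SOS change of one subscore for one paired patient."""

    patient_id: str
    system: str
    subscore: str
    delta: float


def pragma_subscores(annotation: GridAnnotation) -> PragmaScores:
    """Compute PRAGMA-CF volume-fraction subscores from a grid annotation.

    Every subscore is ``100 * (lung cells with that label) / (lung cells)``,
    pooled over all slices; slice and traversal order are irrelevant.
    """
    counts = annotation.label_counts()
    n_lung = sum(c for lab, c in counts.items() if lab.is_lung)
    if n_lung == 0:
        raise ValueError("empty lung: annotation has no lung cells")
    pct = {lab: 100.0 * counts[lab] / n_lung for lab in CellLabel if lab.is_lung}
    return PragmaScores(
        pct_bronchiectasis=pct[CellLabel.BRONCHIECTASIS],
        pct_mucus_plugging=pct[CellLabel.MUCUS_PLUGGING],
        pct_awt=pct[CellLabel.AWT],
        pct_atelectasis=pct[CellLabel.ATELECTASIS],
        pct_normal=pct[CellLabel.NORMAL],
    )


def cfct_scores(
    assessment: LobeAssessmentSet,
    weights: Mapping[str, float] | None = None,
    *,
    allow_nonstandard_weights: bool = False,
) -> CfctScores:
    """Compute CF-CT raw and percent-of-maximum scores.

    ``weights`` maps component -> multiplier on the extent code.  Unless
    ``allow_nonstandard_weights`` is set, weights must reproduce the
    published component maxima 72/54/36/54.
    """
    if weights is None:
        weights = DEFAULT_CFCT_WEIGHTS
    if set(weights) != set(COMPONENTS):
        raise ValueError(f"weights must cover exactly the components {COMPONENTS}")
    maxima = {c: len(REGIONS) * MAX_EXTENT_CODE * weights[c] for c in COMPONENTS}
    if not allow_nonstandard_weights and maxima != CFCT_COMPONENT_MAXIMA:
        raise ValueError(
            "weight table does not reproduce the published component maxima "
            f"{CFCT_COMPONENT_MAXIMA}; pass allow_nonstandard_weights=True to override"
        )
    raw = {
        c: sum(weights[c] * assessment.assessments[(r, c)] for r in REGIONS)
        for c in COMPONENTS
    }
    return CfctScores(raw=raw, maxima=maxima)


def scores_to_frame(
    records: Iterable[tuple[str, str, str, PragmaScores | CfctScores]]
) -> pd.DataFrame:
    """Flatten (patient_id, visit, system, scores) tuples into a tidy table."""
    rows = []
    for pid, visit, system, scores in records:
        for name, value in scores.as_dict().items():
            rows.append((pid, visit, system, name, float(value)))
    return pd.DataFrame(rows, columns=["patient_id", "visit", "system", "subscore", "value"])


def compute_deltas(scores: pd.DataFrame) -> list[DeltaRecord]:
    """EOS minus SOS per subscore for patients with both visits.

    ``scores`` is the tidy score table; patients with a single visit
    contribute nothing.  Duplicate patient-visit-system-subscore records
    are an error.
    """
    required = {"patient_id", "visit", "system", "subscore", "value"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    keys = ["patient_id", "system", "subscore", "visit"]
    dup = scores.duplicated(subset=keys)
    if dup.any():
        offending = scores.loc[dup, keys].iloc[0].tolist()
        raise ValueError(f"duplicate patient-visit-system record: {offending}")
    wide = scores.pivot_table(
        index=["patient_id", "system", "subscore"],
        columns="visit",
        values="value",
        aggfunc="first",
    )
    out: list[DeltaRecord] = []
    if "SOS" not in wide.columns or "EOS" not in wide.columns:
        return out
    paired = wide.dropna(subset=["SOS", "EOS"])
    for (pid, system, subscore), row in paired.iterrows():
        out.append(DeltaRecord(pid, system, subscore, float(row["EOS"] - row["SOS"])))
    return out


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False, lineterminator="\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "visit", "system", "subscore", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"score file {path} missing columns {sorted(missing)}")
    return frame
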
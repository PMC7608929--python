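"""Domain types, validation and file I/O for chest-CT scoring annotations.

Two annotation families are supported:

* **PRAGMA-CF grid annotations** — a rectangular grid is overlaid on 10
  equally spaced axial slices between lung apex and base, and every grid
  cell carries exactly one label.  The labels form a hierarchy (resolved at
  annotation time, so storage is single-label): bronchiectasis > mucus
  plugging > airway wall thickening (AWT) > atelectasis > normal lung;
  cells outside the lung are ``non_lung``.
* **CF-CT lobe assessments** — the five lobes plus the lingula are graded
  per component (bronchiectasis, AWT, mucus plugging, parenchyma) with an
  extent code: 0 absent, 1 for 0-33%, 2 for 33-66%, 3 for >66% of the lobe.

Slice indices, rows and columns are 0-based everywhere (files and APIs).
Label strings are case-insensitive on input and canonical lowercase on
output.

File dialects
-------------
Grid CSV: columns ``patient_id,visit,slice_index,row,col,label``; one row
per cell; cells omitted from the file default to ``non_lung``.  The writer
emits all cells (dense, sorted by patient, visit, slice, row, col) so a
write/read/write cycle is byte-identical.

Grid JSON: ``{patient: {visit: {"slices": [[[label, ...], ...], ...]}}}``.

Lobe CSV: columns ``patient_id,visit,region,component,extent_code``; one
row per (region, component); duplicate rows are accepted only when they
agree (conflicting duplicates are an error).
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CellLabel",
    "GridAnnotation",
    "LobeAssessmentSet",
    "ValidationReport",
    "ParseError",
    "REGIONS",
    "COMPONENTS",
    "N_SLICES",
    "resolve_hierarchy",
    "validate_grid_annotation",
    "read_annotations",
    "write_annotations",
    "read_lobe_assessments",
    "write_lobe_assessments",
]

N_SLICES = 10

REGIONS = ("RUL", "RML", "RLL", "LUL", "lingula", "LLL")
COMPONENTS = ("bronchiectasis", "awt", "mucus_plugging", "parenchyma")
VISITS = ("SOS", "EOS")


class CellLabel(enum.Enum):
    """One label per grid cell; declaration order is hierarchy priority."""

    BRONCHIECTASIS = "bronchiectasis"
    MUCUS_PLUGGING = "mucus_plugging"
    AWT = "awt"
    ATELECTASIS = "atelectasis"
    NORMAL = "normal"
    NON_LUNG = "non_lung"

    @property
    def priority(self) -> int:
        """Hierarchy rank, 0 = highest (bronchiectasis)."""
        return _PRIORITY[self]

    @property
    def is_lung(self) -> bool:
        return self is not CellLabel.NON_LUNG


_PRIORITY = {label: i for i, label in enumerate(CellLabel)}
LABEL_CODES = {label: i for i, label in enumerate(CellLabel)}
CODE_LABELS = {i: label for label, i in LABEL_CODES.items()}
NON_LUNG_CODE = LABEL_CODES[CellLabel.NON_LUNG]

# Input normalization: lowercase with spaces/hyphens collapsed to "_",
# plus the common field abbreviations.
_LABEL_ALIASES = {
    "airway_wall_thickening": "awt",
    "airway_wall_thickness": "awt",
    "be": "bronchiectasis",
    "mp": "mucus_plugging",
    "atl": "atelectasis",
    "normal_lung": "normal",
    "nonlung": "non_lung",
    "non_lung_tissue": "non_lung",
}


class ParseError(ValueError):
    """Malformed annotation file; message names the offending location."""


def parse_label(text: str, *, line: int | None = None) -> CellLabel:
    key = text.strip().lower().replace(" ", "_").replace("-", "_")
    key = _LABEL_ALIASES.get(key, key)
    try:
        return CellLabel(key)
    except ValueError:
        where = f" (line {line})" if line is not None else ""
        raise ParseError(f"unknown cell label {text!r}{where}") from None


def resolve_hierarchy(labels: Iterable[CellLabel]) -> CellLabel:
    """Resolve a multi-label cell to its highest-priority label.

    Bronchiectasis beats mucus plugging beats AWT beats atelectasis beats
    normal lung.  ``non_lung`` is only returned when it is the sole label;
    a cell with any lung label is a lung cell.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cell has no labels")
    lung = [lab for lab in labels if lab.is_lung]
    if not lung:
        return CellLabel.NON_LUNG
    return min(lung, key=lambda lab: lab.priority)


@dataclass(eq=False)
class GridAnnotation:
    """One patient-visit PRAGMA-CF annotation: 10 labelled slice grids.

    ``slices`` holds one ``uint8`` array of label codes per axial slice
    (see :data:`LABEL_CODES`); all slices share the same grid shape.
    """

    patient_id: str
    visit: str
    slices: list[np.ndarray]

    @classmethod
    def from_labels(
        cls, patient_id: str, visit: str, slices: Sequence[Sequence[Sequence[CellLabel]]]
    ) -> "GridAnnotation":
        arrays = [
            np.array([[LABEL_CODES[lab] for lab in row] for row in sl], dtype=np.uint8)
            for sl in slices
        ]
        return cls(patient_id, visit, arrays)

    @property
    def grid_rows(self) -> int:
        return int(self.slices[0].shape[0])

    @property
    def grid_cols(self) -> int:
        return int(self.slices[0].shape[1])

    def label_counts(self) -> dict[CellLabel, int]:
        counts = np.zeros(len(CellLabel), dtype=np.int64)
        for sl in self.slices:
            counts += np.bincount(sl.ravel(), minlength=len(CellLabel))
        return {CODE_LABELS[i]: int(c) for i, c in enumerate(counts)}

    def n_lung_cells(self) -> int:
        return sum(c for lab, c in self.label_counts().items() if lab.is_lung)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridAnnotation):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.visit == other.visit
            and len(self.slices) == len(other.slices)
            and all(np.array_equal(a, b) for a, b in zip(self.slices, other.slices))
        )


@dataclass(frozen=True)
class LobeAssessmentSet:
    """One patient-visit CF-CT assessment: extent codes per region/component."""

    patient_id: str
    visit: str
    assessments: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        missing = [
            (r, c)
            for r in REGIONS
            for c in COMPONENTS
            if (r, c) not in self.assessments
        ]
        if missing:
            raise ValueError(
                f"incomplete assessment for {self.patient_id}/{self.visit}: "
                f"missing {missing}"
            )
        for key, code in self.assessments.items():
            if code not in (0, 1, 2, 3):
                raise ValueError(f"extent_code {code} out of range 0-3 for {key}")

    @classmethod
    def uniform(cls, patient_id: str, visit: str, extent_code: int) -> "LobeAssessmentSet":
        return cls(
            patient_id,
            visit,
            {(r, c): extent_code for r in REGIONS for c in COMPONENTS},
        )


@dataclass
class ValidationReport:
    """Findings from structural validation; ``valid`` iff no error."""

    issues: list[tuple[str, str]] = field(default_factory=list)  # (severity, message)

    @property
    def valid(self) -> bool:
        return not any(sev == "error" for sev, _ in self.issues)

    def error(self, message: str) -> None:
        self.issues.append(("error", message))

    def warning(self, message: str) -> None:
        self.issues.append(("warning", message))


def validate_grid_annotation(annotation: GridAnnotation) -> ValidationReport:
    """Check the structural invariants of a grid annotation.

    All problems are reported in the returned :class:`ValidationReport`;
    nothing is raised.
    """
    report = ValidationReport()
    if annotation.visit not in VISITS:
        report.error(f"unknown visit {annotation.visit!r}; expected one of {VISITS}")
    n = len(annotation.slices)
    if n != N_SLICES:
        report.error(f"expected {N_SLICES} slices, found {n}")
    if n == 0:
        return report
    shapes = {sl.shape for sl in annotation.slices}
    if len(shapes) > 1:
        report.error(f"slices do not share grid dimensions: {sorted(shapes)}")
    for i, sl in enumerate(annotation.slices):
        if sl.ndim != 2 or sl.size == 0:
            report.error(f"slice {i} is not a non-empty rectangular grid")
        elif sl.max(initial=0) >= len(CellLabel):
            report.error(f"slice {i} contains invalid label codes")
    if annotation.n_lung_cells() == 0:
        report.error("no lung cells (all cells non_lung)")
    return report


# ---------------------------------------------------------------------------
# Grid annotation I/O

_GRID_HEADER = ["patient_id", "visit", "slice_index", "row", "col", "label"]


def write_annotations(
    annotations: Sequence[GridAnnotation], path: str | Path, format: str = "csv"
) -> None:
    """Write grid annotations in the canonical dense dialect."""
    path = Path(path)
    ordered = sorted(annotations, key=lambda a: (a.patient_id, a.visit))
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(_GRID_HEADER)
            for ann in ordered:
                for s, sl in enumerate(ann.slices):
                    for r in range(sl.shape[0]):
                        for c in range(sl.shape[1]):
                            writer.writerow(
                                [
                                    ann.patient_id,
                                    ann.visit,
                                    s,
                                    r,
                                    c,
                                    CODE_LABELS[int(sl[r, c])].value,
                                ]
                            )
    elif format == "json":
        payload: dict = {}
        for ann in ordered:
            payload.setdefault(ann.patient_id, {})[ann.visit] = {
                "slices": [
                    [[CODE_LABELS[int(v)].value for v in row] for row in sl]
                    for sl in ann.slices
                ]
            }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path: str | Path, format: str = "csv") -> list[GridAnnotation]:
    """Read grid annotations written in the documented CSV or JSON dialect."""
    path = Path(path)
    if format == "csv":
        return _read_annotations_csv(path)
    if format == "json":
        return _read_annotations_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_annotations_csv(path: Path) -> list[GridAnnotation]:
    cells: dict[tuple[str, str], dict[tuple[int, int, int], int]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _GRID_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(_GRID_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns, got {len(row)}")
            pid, visit, s, r, c, label = row
            try:
                s_i, r_i, c_i = int(s), int(r), int(c)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer index: {exc}") from None
            if min(s_i, r_i, c_i) < 0:
                raise ParseError(f"{path}: line {lineno}: negative index")
            code = LABEL_CODES[parse_label(label, line=lineno)]
            block = cells.setdefault((pid, visit), {})
            key = (s_i, r_i, c_i)
            if key in block and block[key] != code:
                raise ParseError(
                    f"{path}: line {lineno}: conflicting duplicate cell "
                    f"(patient {pid}, visit {visit}, slice {s_i}, row {r_i}, col {c_i})"
                )
            block[key] = code
    annotations = []
    for (pid, visit), block in sorted(cells.items()):
        n_slices = max(k[0] for k in block) + 1
        rows = max(k[1] for k in block) + 1
        cols = max(k[2] for k in block) + 1
        slices = [
            np.full((rows, cols), NON_LUNG_CODE, dtype=np.uint8) for _ in range(n_slices)
        ]
        for (s, r, c), code in block.items():
            slices[s][r, c] = code
        annotations.append(GridAnnotation(pid, visit, slices))
    return annotations


def _read_annotations_json(path: Path) -> list[GridAnnotation]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    annotations = []
    for pid in sorted(payload):
        for visit in sorted(payload[pid]):
            entry = payload[pid][visit]
            if "slices" not in entry:
                raise ParseError(f"{path}: {pid}/{visit}: missing 'slices'")
            slices = []
            for s, sl in enumerate(entry["slices"]):
                try:
                    arr = np.array(
                        [[LABEL_CODES[parse_label(v)] for v in row] for row in sl],
                        dtype=np.uint8,
                    )
                except ParseError:
                    raise
                if arr.ndim != 2:
                    raise ParseError(f"{path}: {pid}/{visit}: slice {s} is not rectangular")
                slices.append(arr)
            annotations.append(GridAnnotation(pid, visit, slices))
    return annotations


# ---------------------------------------------------------------------------
# Lobe assessment I/O

_LOBE_HEADER = ["patient_id", "visit", "region", "component", "extent_code"]


def write_lobe_assessments(
    assessments: Sequence[LobeAssessmentSet], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_LOBE_HEADER)
        for a in sorted(assessments, key=lambda a: (a.patient_id, a.visit)):
            for region in REGIONS:
                for component in COMPONENTS:
                    writer.writerow(
                        [a.patient_id, a.visit, region, component, a.assessments[(region, component)]]
                    )


def read_lobe_assessments(path: str | Path) -> list[LobeAssessmentSet]:
    """Read CF-CT lobe assessments; every patient-visit must have 24 entries."""
    path = Path(path)
    blocks: dict[tuple[str, str], dict[tuple[str, str], int]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _LOBE_HEADER:
            raise ParseError(
                f"{path}: expected header {','.join(_LOBE_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(f"{path}: line {lineno}: expected 5 columns, got {len(row)}")
            pid, visit, region, component, code_s = row
            if region not in REGIONS:
                raise ParseError(f"{path}: line {lineno}: unknown region {region!r}")
            component = component.strip().lower().replace(" ", "_").replace("-", "_")
            component = _LABEL_ALIASES.get(component, component)
            if component not in COMPONENTS:
                raise ParseError(f"{path}: line {lineno}: unknown component {row[3]!r}")
            try:
                code = int(code_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer extent_code {code_s!r}"
                ) from None
            if code not in (0, 1, 2, 3):
                raise ParseError(
                    f"{path}: line {lineno}: extent_code {code} out of range 0-3"
                )
            block = blocks.setdefault((pid, visit), {})
            key = (region, component)
            if key in block and block[key] != code:
                raise ParseError(
                    f"{path}: line {lineno}: conflicting duplicate for "
                    f"(patient {pid}, visit {visit}, region {region}, component {component})"
                )
            block[key] = code
    out = []
    for (pid, visit), block in sorted(blocks.items()):
        missing = [(r, c) for r in REGIONS for c in COMPONENTS if (r, c) not in block]
        if missing:
            raise ParseError(
                f"{path}: incomplete assessment for {pid}/{visit}: missing {missing}"
            )
        out.append(LobeAssessmentSet(pid, visit, block))
    return out
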
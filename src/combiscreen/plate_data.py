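"""Data model and tabular I/O for cell-viability plate records.

A viability screen produces one signal per well: an MTS optical density
(absorbance at 492 nm, proportional to metabolically active cells) or an
alamarBlue percent dye reduction. Wells are identified by cell line,
treatment arm (miRNA mimic and/or drug at a dose), experiment repeat and
replicate well. All downstream stages (MAD hit calling, dose-response
fitting, interaction testing) consume collections of
:class:`ViabilityRecord`.

The on-disk format is a long CSV/TSV with columns::

    cell_line, mirna, drug, dose, dose_unit, repeat_id, well_id, assay, signal

Empty strings in ``mirna``/``drug`` mean "not applied"; the sentinel
``NEG_CONTROL`` marks negative-control transfections. Doses are converted
to molar on load (the unit column accepts pM/nM/uM/mM/M).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "Assay",
    "NEG_CONTROL",
    "REQUIRED_COLUMNS",
    "ViabilityRecord",
    "ExperimentDesign",
    "read_viability_table",
    "write_viability_table",
    "group_arms",
]

#: Sentinel identifier for negative-control (scrambled) transfections.
NEG_CONTROL = "NEG_CONTROL"

#: Exact column names required in input tables.
REQUIRED_COLUMNS = (
    "cell_line",
    "mirna",
    "drug",
    "dose",
    "dose_unit",
    "repeat_id",
    "well_id",
    "assay",
    "signal",
)

_UNIT_TO_MOLAR = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "μm": 1e-6, "nm": 1e-9, "pm": 1e-12}


class Assay(str, Enum):
    """Viability readout type: MTS optical density or alamarBlue % reduction."""

    MTS = "MTS"
    ALAMAR = "ALAMAR"


@dataclass(frozen=True, slots=True)
class ViabilityRecord:
    """One well's viability readout.

    ``mirna`` is ``None`` for untransfected wells, :data:`NEG_CONTROL` for
    scrambled-control transfections, otherwise a miRNA identifier.
    ``drug`` is ``None`` for drug-free wells. ``dose`` is in molar and must
    be 0 when no drug was applied.
    """

    cell_line: str
    mirna: str | None
    drug: str | None
    dose: float
    repeat_id: int
    well_id: int
    assay: Assay
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError(f"signal must be >= 0, got {self.signal}")
        if self.dose < 0:
            raise ValidationError(f"dose must be >= 0, got {self.dose}")
        if self.dose > 0 and self.drug is None:
            raise ValidationError("dose > 0 requires a drug identifier")

    @property
    def key(self) -> tuple:
        """Uniqueness key within a dataset."""
        return (
            self.cell_line,
            self.mirna,
            self.drug,
            self.dose,
            self.repeat_id,
            self.well_id,
            self.assay,
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """The comparison family of one cell line's combination experiment.

    The Bonferroni families are defined by the number of drugs tested
    (interaction calls) and the number of miRNAs tested (single-agent
    calls), so both counts are derived directly from the treatment lists.
    """

    cell_line: str
    mirnas: tuple[str, ...]
    drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.mirnas or not self.drugs:
            raise ValidationError("design needs at least one miRNA and one drug")

    @property
    def n_drug_comparisons(self) -> int:
        return len(self.drugs)

    @property
    def n_mirna_comparisons(self) -> int:
        return len(self.mirnas)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        """Load a design from YAML with keys ``cell_line``, ``mirnas``, ``drugs``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(
                cell_line=str(raw["cell_line"]),
                mirnas=tuple(str(m) for m in raw["mirnas"]),
                drugs=tuple(str(d) for d in raw["drugs"]),
            )
        except KeyError as exc:  # pragma: no cover - trivial
            raise SchemaError(f"design file {path} is missing key {exc}") from exc


def _dose_to_molar(dose: float, unit: str, row: int) -> float:
    factor = _UNIT_TO_MOLAR.get(str(unit).strip().lower())
    if factor is None:
        raise ValidationError(f"row {row}: unknown dose_unit {unit!r} (expected pM/nM/uM/mM/M)")
    return dose * factor


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_viability_table(
    path: str | Path, assay: Assay | str | None = None
) -> list[ViabilityRecord]:
    """Read a long-format viability table into validated records.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab, by extension) file with the columns in
        :data:`REQUIRED_COLUMNS`.
    assay
        If given, keep only rows of that assay.

    Raises
    ------
    SchemaError
        If a required column is missing (the message names it).
    ValidationError
        On a negative signal/dose, unknown unit, bad assay label or a
        duplicate well key; messages cite the 1-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), keep_default_na=False, dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"input table {path} is missing required column {col!r}")
    want = Assay(assay) if assay is not None and not isinstance(assay, Assay) else assay

    records: list[ViabilityRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            rec_assay = Assay(str(row.assay).strip().upper())
        except ValueError:
            raise ValidationError(f"row {i}: unknown assay {row.assay!r}") from None
        if want is not None and rec_assay is not want:
            continue
        try:
            dose = float(row.dose)
            signal = float(row.signal)
        except ValueError as exc:
            raise ValidationError(f"row {i}: non-numeric dose or signal") from exc
        try:
            rec = ViabilityRecord(
                cell_line=str(row.cell_line),
                mirna=str(row.mirna) or None,
                drug=str(row.drug) or None,
                dose=_dose_to_molar(dose, str(row.dose_unit), i) if dose else 0.0,
                repeat_id=int(row.repeat_id),
                well_id=int(row.well_id),
                assay=rec_assay,
                signal=signal,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        if rec.key in seen:
            raise ValidationError(f"row {i}: duplicate well key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_viability_table(records: Iterable[ViabilityRecord], path: str | Path) -> None:
    """Write records in the canonical long format (doses in molar)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in records],
            "mirna": [r.mirna if r.mirna is not None else "" for r in records],
            "drug": [r.drug if r.drug is not None else "" for r in records],
            "dose": [repr(r.dose) for r in records],
            "dose_unit": ["M" for r in records],
            "repeat_id": [r.repeat_id for r in records],
            "well_id": [r.well_id for r in records],
            "assay": [r.assay.value for r in records],
            "signal": [repr(r.signal) for r in records],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def group_arms(
    records: Sequence[ViabilityRecord],
    cell_line: str,
    assay: Assay | None = None,
) -> dict[tuple[str | None, str | None], list[float]]:
    """Pool well signals per treatment arm ``(mirna, drug)`` for one cell line.

    Each well contributes exactly one signal to exactly one arm; repeat and
    well indices are ignored, i.e. duplicates across experiment repeats are
    pooled into one observation list per arm.
    """
    known = {r.cell_line for r in records}
    if cell_line not in known:
        raise KeyError(f"cell line {cell_line!r} not present (have {sorted(known)})")
    arms: dict[tuple[str | None, str | None], list[float]] = {}
    for r in records:
        if r.cell_line != cell_line:
            continue
        if assay is not None and r.assay is not assay:
            continue
        arms.setdefault((r.mirna, r.drug), []).append(r.signal)
    return arms
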
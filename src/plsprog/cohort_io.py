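"""Patient cohort data model and CSV/TSV readers and writers.

A cohort is an ordered collection of :class:`ClinicalRecord` objects, one per
patient, optionally paired with per-patient qPCR expression profiles (fold
change of each candidate transcript before and after MALAT1 silencing,
relative to the LacZ-gapmer control).

Adverse histopathologic flags (lymphovascular invasion, positive surgical
margins, extracapsular extension, perineural invasion) are ternary: ``True``,
``False`` or ``None`` (unknown). Missingness is representable on purpose —
downstream feature assembly uses listwise deletion, so "unknown" must never
silently collapse to "absent".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .expression_features import ExpressionProfile, GENES

__all__ = [
    "ClinicalRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortRowError",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "load_table1_fixture",
]

#: Mandatory clinical columns of the cohort table, in canonical order.
COHORT_COLUMNS = [
    "patient_id",
    "age",
    "serum_psa",
    "gleason_primary",
    "gleason_secondary",
    "pathological_stage",
    "lvi",
    "margins",
    "ece",
    "pni",
    "recurrence",
    "time_to_recurrence",
]

class CohortSchemaError(ValueError):
    """The table is missing a mandatory column or is structurally invalid."""


class CohortRowError(ValueError):
    """A data row could not be parsed; carries the offending row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class ClinicalRecord:
    """Demographic, histopathologic and outcome fields for one patient.

    ``time_to_recurrence`` is months since prostatectomy; the four adverse
    flags are ``True``/``False``/``None`` (unknown).
    """

    patient_id: str
    age: int
    serum_psa: float
    gleason_primary: int
    gleason_secondary: int
    pathological_stage_raw: str
    lymphovascular_invasion: bool | None = None
    surgical_margins_positive: bool | None = None
    extracapsular_extension: bool | None = None
    perineural_invasion: bool | None = None
    recurrence: bool = False
    time_to_recurrence: float | None = None

    def __post_init__(self) -> None:
        if self.serum_psa < 0:
            raise ValueError(f"serum_psa must be >= 0, got {self.serum_psa}")
        if not (3 <= self.gleason_primary <= 5 and 3 <= self.gleason_secondary <= 5):
            raise ValueError(
                "Gleason patterns must be in 3..5, got "
                f"{self.gleason_primary}+{self.gleason_secondary}"
            )
        gsum = self.gleason_primary + self.gleason_secondary
        if not 6 <= gsum <= 10:
            raise ValueError(f"Gleason sum must be in 6..10, got {gsum}")
        if self.time_to_recurrence is not None and self.time_to_recurrence <= 0:
            raise ValueError("time_to_recurrence must be positive when present")

    @property
    def adverse_flags(self) -> tuple[bool | None, bool | None, bool | None, bool | None]:
        """(LVI, margins, ECE, PNI) in score-weight order."""
        return (
            self.lymphovascular_invasion,
            self.surgical_margins_positive,
            self.extracapsular_extension,
            self.perineural_invasion,
        )


@dataclass
class Cohort:
    """Ordered patient records plus optional per-patient expression profiles."""

    records: list[ClinicalRecord] = field(default_factory=list)
    expression: dict[str, ExpressionProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids: {dupes}")
        stray = set(self.expression) - set(ids)
        if stray:
            raise ValueError(f"expression profiles without records: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ClinicalRecord]:
        return iter(self.records)

    def __getitem__(self, patient_id: str) -> ClinicalRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        """New cohort restricted to ``patient_ids``, original order preserved."""
        keep = set(patient_ids)
        recs = [r for r in self.records if r.patient_id in keep]
        expr = {i: p for i, p in self.expression.items() if i in keep}
        return Cohort(records=recs, expression=expr)


def _parse_flag(cell: object) -> bool | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    s = str(cell).strip().lower()
    if s in ("", "nan", "na", "unknown", "?"):
        return None
    if s in ("true", "t", "yes", "y", "1", "1.0", "pos", "positive"):
        return True
    if s in ("false", "f", "no", "n", "0", "0.0", "-", "neg", "negative"):
        return False
    raise ValueError(f"unparseable ternary flag {cell!r}")


def _format_flag(v: bool | None) -> str:
    return "" if v is None else ("true" if v else "false")


def read_cohort(path: str | Path, dialect: str = ",") -> Cohort:
    """Read a cohort table from ``path``.

    Parameters
    ----------
    path
        CSV/TSV file with a header row. Mandatory columns are
        :data:`COHORT_COLUMNS`; optional expression columns are named
        ``<gene>_basal`` and ``<gene>_silenced`` for each candidate gene.
    dialect
        Field delimiter, ``","`` (default) or ``"\\t"``.

    Raises
    ------
    CohortSchemaError
        If a mandatory column is absent (the message names it).
    CohortRowError
        If a numeric cell cannot be parsed (carries the 0-based row index).
    """
    df = pd.read_csv(path, sep=dialect, dtype=str, keep_default_na=False)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise CohortSchemaError(f"missing mandatory column: {col!r}")

    records: list[ClinicalRecord] = []
    expression: dict[str, ExpressionProfile] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        try:
            ttr_cell = row["time_to_recurrence"].strip()
            rec = ClinicalRecord(
                patient_id=row["patient_id"].strip(),
                age=int(float(row["age"])),
                serum_psa=float(row["serum_psa"]),
                gleason_primary=int(float(row["gleason_primary"])),
                gleason_secondary=int(float(row["gleason_secondary"])),
                pathological_stage_raw=row["pathological_stage"].strip(),
                lymphovascular_invasion=_parse_flag(row["lvi"]),
                surgical_margins_positive=_parse_flag(row["margins"]),
                extracapsular_extension=_parse_flag(row["ece"]),
                perineural_invasion=_parse_flag(row["pni"]),
                recurrence=bool(_parse_flag(row["recurrence"])),
                time_to_recurrence=float(ttr_cell) if ttr_cell else None,
            )
        except (ValueError, TypeError) as exc:
            raise CohortRowError(idx, str(exc)) from exc
        records.append(rec)

        gene_vals: dict[str, tuple[float | None, float | None]] = {}
        for gene in GENES:
            basal = row.get(f"{gene}_basal", "").strip()
            silenced = row.get(f"{gene}_silenced", "").strip()
            if basal or silenced:
                try:
                    gene_vals[gene] = (
                        float(basal) if basal else None,
                        float(silenced) if silenced else None,
                    )
                except ValueError as exc:
                    raise CohortRowError(idx, f"gene {gene}: {exc}") from exc
        if gene_vals:
            expression[rec.patient_id] = ExpressionProfile(
                basal_fc={g: v[0] for g, v in gene_vals.items() if v[0] is not None},
                silenced_fc={g: v[1] for g, v in gene_vals.items() if v[1] is not None},
            )

    return Cohort(records=records, expression=expression)


def write_cohort(cohort: Cohort, path: str | Path, dialect: str = ",") -> None:
    """Write ``cohort`` so that :func:`read_cohort` reproduces it exactly.

    Unknown flags and absent values are written as empty cells. Expression
    columns are emitted only if at least one patient carries a profile.
    """
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")

    has_expr = bool(cohort.expression)
    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "serum_psa": _fmt_num(rec.serum_psa),
            "gleason_primary": rec.gleason_primary,
            "gleason_secondary": rec.gleason_secondary,
            "pathological_stage": rec.pathological_stage_raw,
            "lvi": _format_flag(rec.lymphovascular_invasion),
            "margins": _format_flag(rec.surgical_margins_positive),
            "ece": _format_flag(rec.extracapsular_extension),
            "pni": _format_flag(rec.perineural_invasion),
            "recurrence": "true" if rec.recurrence else "false",
            "time_to_recurrence": (
                _fmt_num(rec.time_to_recurrence)
                if rec.time_to_recurrence is not None
                else ""
            ),
        }
        if has_expr:
            prof = cohort.expression.get(rec.patient_id)
            for gene in GENES:
                b = prof.basal_fc.get(gene) if prof else None
                s = prof.silenced_fc.get(gene) if prof else None
                row[f"{gene}_basal"] = _fmt_num(b) if b is not None else ""
                row[f"{gene}_silenced"] = _fmt_num(s) if s is not None else ""
        rows.append(row)

    cols = list(COHORT_COLUMNS)
    if has_expr:
        for gene in GENES:
            cols += [f"{gene}_basal", f"{gene}_silenced"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=dialect, index=False)


def _fmt_num(x: float) -> str:
    # repr round-trips floats exactly; integers render without trailing ".0"
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def load_table1_fixture() -> Cohort:
    """Load the packaged 50-patient clinical table.

    The source table prints only age, serum PSA, Gleason patterns, stage,
    recurrence and time to recurrence — the four adverse flags are therefore
    unknown for every patient. One patient (id 37) is printed with no
    recurrence but a 5-month recurrence time; the row is kept verbatim and a
    data-quality warning is emitted.
    """
    ref = resources.files("plsprog") / "data" / "table1.csv"
    with resources.as_file(ref) as p:
        cohort = read_cohort(p)
    for rec in cohort.records:
        if not rec.recurrence and rec.time_to_recurrence is not None:
            warnings.warn(
                f"patient {rec.patient_id}: time_to_recurrence="
                f"{rec.time_to_recurrence} printed without a recurrence event; "
                "kept verbatim",
                UserWarning,
                stacklevel=2,
            )
    return cohort
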
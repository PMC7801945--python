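"""Composite clinical variables and feature-matrix assembly.

Two ordinal composites summarise the histopathology:

* the pathological-stage code, mapping pT2a..pT3b to 1..5;
* the adverse-clinical-features score, a weighted sum of four adverse
  findings (lymphovascular invasion, positive surgical margins,
  extracapsular extension, perineural invasion) with weights 1, 2, 3 and
  0.5, so the score ranges over 0..6.5.

Three feature sets ("criteria") feed the PLS-DA classifier:

* ``classical`` — age, serum PSA, ISUP grade group, stage code, adverse
  score: what a clinician has without any molecular assay;
* ``new`` — classical plus basal expression of the seven candidate
  transcripts;
* ``new_bis`` — new plus the silenced/basal modulation ratios of ME3,
  PDK3, PDK1 and PSA, available only after the silencing experiment.

Rows with any unknown value in the selected columns are removed (listwise
deletion) and the dropped ids reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

import numpy as np

from .cohort_io import ClinicalRecord, Cohort
from .expression_features import GENES, RATIO_GENES

__all__ = [
    "AdverseFeatureWeights",
    "STAGE_CODES",
    "CRITERIA",
    "FeatureMatrix",
    "InsufficientDataError",
    "encode_pathological_stage",
    "gleason_to_isup",
    "adverse_clinical_features_score",
    "assemble_feature_matrix",
]

#: Ordinal codes of the pathological sub-stages.
STAGE_CODES = {"pT2a": 1, "pT2b": 2, "pT2c": 3, "pT3a": 4, "pT3b": 5}

CRITERIA = ("classical", "new", "new_bis")

_CLASSICAL_COLUMNS = ["age", "serum_psa", "isup", "stage_code", "adverse_score"]


@dataclass(frozen=True)
class AdverseFeatureWeights:
    """Weights of the four adverse findings in the composite score."""

    w_lvi: float = 1.0
    w_margins: float = 2.0
    w_ece: float = 3.0
    w_pni: float = 0.5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    @property
    def total(self) -> float:
        return self.w_lvi + self.w_margins + self.w_ece + self.w_pni

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_lvi, self.w_margins, self.w_ece, self.w_pni)


class InsufficientDataError(ValueError):
    """Too few complete rows per class to build a usable feature matrix."""


@dataclass
class FeatureMatrix:
    """Complete-case numeric feature matrix with labels and row/column names."""

    values: np.ndarray  # n x p, float
    column_names: list[str]
    labels: np.ndarray  # n bool, True = recurrent
    row_ids: list[str]
    dropped_ids: list[str]  # removed by listwise deletion

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        n, p = self.values.shape
        if len(self.column_names) != p or len(self.labels) != n or len(self.row_ids) != n:
            raise ValueError("values, column_names, labels and row_ids misaligned")
        if len(set(self.column_names)) != p:
            raise ValueError("duplicate column names")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


_STAGE_TOKEN = re.compile(r"^p?T(\d)([a-c])$", re.IGNORECASE)


def encode_pathological_stage(stage_raw: str) -> int | None:
    """Ordinal 1..5 for a pathological T-stage string, None if unmappable.

    Tokenizes the string, normalises a leading "T" to "pT", ignores N/M
    tokens, and looks up the sub-stage. A T stage printed without its
    sub-stage letter (e.g. "T2 Nx Mx") carries no rank within 1..5 and maps
    to None.
    """
    for token in str(stage_raw).split():
        m = _STAGE_TOKEN.match(token)
        if m:
            key = f"pT{m.group(1)}{m.group(2).lower()}"
            return STAGE_CODES.get(key)
    return None


def gleason_to_isup(primary: int, secondary: int) -> int:
    """ISUP grade group 1..5 from Gleason primary + secondary patterns.

    Standard grade-group table: 3+3 -> 1, 3+4 -> 2, 4+3 -> 3, sum 8 -> 4,
    sum 9-10 -> 5.
    """
    if not (3 <= primary <= 5 and 3 <= secondary <= 5):
        raise ValueError(f"Gleason patterns must be in 3..5, got {primary}+{secondary}")
    total = primary + secondary
    if total == 6:
        return 1
    if total == 7:
        return 2 if primary == 3 else 3
    if total == 8:
        return 4
    return 5


def adverse_clinical_features_score(
    flags: tuple[bool | None, bool | None, bool | None, bool | None],
    weights: AdverseFeatureWeights = AdverseFeatureWeights(),
) -> float | None:
    """Weighted sum of positive adverse findings, None if any flag is unknown.

    ``flags`` is (LVI, margins, ECE, PNI), matching the weight order. With
    default weights the score spans 0 (no adverse finding) to 6.5 (all four
    positive).
    """
    if any(f is None for f in flags):
        return None
    return sum(w for f, w in zip(flags, weights.as_tuple()) if f)


def _record_features(
    rec: ClinicalRecord, weights: AdverseFeatureWeights
) -> dict[str, float | None]:
    return {
        "age": float(rec.age),
        "serum_psa": rec.serum_psa,
        "isup": float(gleason_to_isup(rec.gleason_primary, rec.gleason_secondary)),
        "stage_code": (
            float(c) if (c := encode_pathological_stage(rec.pathological_stage_raw)) else None
        ),
        "adverse_score": adverse_clinical_features_score(rec.adverse_flags, weights),
    }


def assemble_feature_matrix(
    cohort: Cohort,
    criterium: str,
    weights: AdverseFeatureWeights = AdverseFeatureWeights(),
) -> FeatureMatrix:
    """Build the complete-case feature matrix for one criterium.

    Column sets: classical = {age, serum_psa, isup, stage_code,
    adverse_score}; new = classical + basal fold changes of the seven
    candidate genes; new_bis = new + modulation ratios of ME3, PDK3, PDK1
    and PSA. Patients with any unknown value among the selected columns are
    dropped (listwise deletion) and reported in ``dropped_ids``.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 complete rows remain in either outcome class.
    """
    if criterium not in CRITERIA:
        raise ValueError(f"unknown criterium {criterium!r}; expected one of {CRITERIA}")

    columns = list(_CLASSICAL_COLUMNS)
    if criterium in ("new", "new_bis"):
        columns += [f"{g}_basal" for g in GENES]
    if criterium == "new_bis":
        columns += [f"ratio_{g}" for g in RATIO_GENES]

    rows: list[list[float]] = []
    labels: list[bool] = []
    row_ids: list[str] = []
    dropped: list[str] = []
    for rec in cohort.records:
        feats = _record_features(rec, weights)
        if criterium in ("new", "new_bis"):
            prof = cohort.expression.get(rec.patient_id)
            for g in GENES:
                feats[f"{g}_basal"] = prof.basal_fc.get(g) if prof else None
            if criterium == "new_bis":
                for g in RATIO_GENES:
                    feats[f"ratio_{g}"] = prof.ratio(g) if prof else None
        vals = [feats[c] for c in columns]
        if any(v is None for v in vals):
            dropped.append(rec.patient_id)
            continue
        rows.append([float(v) for v in vals])
        labels.append(rec.recurrence)
        row_ids.append(rec.patient_id)

    lab = np.array(labels, dtype=bool)
    if lab.sum() < 2 or (~lab).sum() < 2:
        raise InsufficientDataError(
            f"criterium {criterium!r}: need >= 2 complete rows per class, got "
            f"{int(lab.sum())} recurrent / {int((~lab).sum())} non-recurrent"
        )
    return FeatureMatrix(
        values=np.array(rows, dtype=float),
        column_names=columns,
        labels=lab,
        row_ids=row_ids,
        dropped_ids=dropped,
    )
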
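"""qPCR-derived quantities.

Relative expression is handled throughout as fold change versus the LacZ
gapmer control (control == 1), the usual output of the comparative-Ct
(2^-ddCt) method with perfect amplification efficiency assumed. Silencing
efficiency, the depletion filter used to define the efficiently silenced
subsample, per-gene modulation ratios, and relative mitochondrial DNA
content are all computed from those fold changes or from raw Ct values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_io import Cohort

__all__ = [
    "GENES",
    "RATIO_GENES",
    "ExpressionProfile",
    "CtQuadruple",
    "ddct_fold_change",
    "silencing_efficiency",
    "filter_silenced",
    "modulation_ratio",
    "mtdna_content_ratio",
]

#: Candidate transcripts assayed before/after MALAT1 silencing.
GENES = ("MALAT1", "ME3", "PDK3", "PDK1", "CHKA", "PS2", "PSA")

#: Genes whose silenced/basal modulation ratio is itself a prognostic feature.
RATIO_GENES = ("ME3", "PDK3", "PDK1", "PSA")


@dataclass
class ExpressionProfile:
    """Per-gene fold changes for one patient.

    ``basal_fc`` is expression before MALAT1 silencing, ``silenced_fc``
    after, both relative to the LacZ-gapmer control. Genes may be missing
    from either mapping (assay dropout); present values must be positive.
    """

    basal_fc: dict[str, float] = field(default_factory=dict)
    silenced_fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping in (("basal_fc", self.basal_fc), ("silenced_fc", self.silenced_fc)):
            for gene, fc in mapping.items():
                if not fc > 0:
                    raise ValueError(f"{name}[{gene}] must be > 0, got {fc}")

    def ratio(self, gene: str) -> float | None:
        """Modulation ratio silenced/basal for ``gene``, or None if either is missing."""
        b = self.basal_fc.get(gene)
        s = self.silenced_fc.get(gene)
        if b is None or s is None:
            return None
        return modulation_ratio(s, b)


@dataclass(frozen=True)
class CtQuadruple:
    """The four threshold cycles of a comparative-Ct quantification."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float


def ddct_fold_change(ct: CtQuadruple) -> float:
    """Fold change 2^-ddCt of target in treated vs control samples.

    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control.
    Shifting all four Cts by a constant leaves the result unchanged.
    """
    ddct = (ct.ct_target_treated - ct.ct_reference_treated) - (
        ct.ct_target_control - ct.ct_reference_control
    )
    return 2.0 ** (-ddct)


def silencing_efficiency(malat1_fc: float) -> float:
    """Percent MALAT1 depletion: (1 - fold_change) * 100.

    Negative when expression rose under the targeting gapmer.
    """
    if not malat1_fc > 0:
        raise ValueError(f"fold change must be > 0, got {malat1_fc}")
    return (1.0 - malat1_fc) * 100.0


def filter_silenced(
    cohort: "Cohort", threshold_percent: float = 17.0
) -> tuple["Cohort", list[str]]:
    """Keep patients whose MALAT1 depletion is >= ``threshold_percent``.

    The threshold is inclusive. Patients without a MALAT1 silenced fold
    change are excluded with a warning. Returns the retained sub-cohort
    (order preserved) and the list of dropped patient ids.
    """
    keep: list[str] = []
    dropped: list[str] = []
    for rec in cohort.records:
        prof = cohort.expression.get(rec.patient_id)
        fc = prof.silenced_fc.get("MALAT1") if prof else None
        if fc is None:
            warnings.warn(
                f"patient {rec.patient_id}: no MALAT1 silenced fold change; "
                "excluded from the silenced subsample",
                UserWarning,
                stacklevel=2,
            )
            dropped.append(rec.patient_id)
        elif silencing_efficiency(fc) >= threshold_percent:
            keep.append(rec.patient_id)
        else:
            dropped.append(rec.patient_id)
    return cohort.subset(keep), dropped


def modulation_ratio(silenced_fc: float, basal_fc: float) -> float:
    """Expression after MALAT1 silencing divided by basal expression."""
    if not (silenced_fc > 0 and basal_fc > 0):
        raise ValueError("fold changes must be > 0")
    return silenced_fc / basal_fc


def mtdna_content_ratio(ct_nd1: float, ct_rplp0: float) -> float:
    """Relative mitochondrial DNA content from mitochondrial ND1 vs nuclear RPLP0 Cts.

    Computed as 2^(Ct_RPLP0 - Ct_ND1): an ND1 amplifying one cycle earlier
    than RPLP0 means twice the mtDNA content.
    """
    return 2.0 ** (ct_rplp0 - ct_nd1)
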
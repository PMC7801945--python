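import numpy as np
import pytest

from plsprog.cohort_io import ClinicalRecord, Cohort
from plsprog.expression_features import GENES, ExpressionProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_record(pid="p1", recurrence=False, **kw):
    defaults = dict(
        patient_id=pid,
        age=65,
        serum_psa=8.0,
        gleason_primary=3,
        gleason_secondary=4,
        pathological_stage_raw="pT2c N0 Mx",
        lymphovascular_invasion=False,
        surgical_margins_positive=False,
        extracapsular_extension=False,
        perineural_invasion=False,
        recurrence=recurrence,
        time_to_recurrence=6.0 if recurrence else None,
    )
    defaults.update(kw)
    return ClinicalRecord(**defaults)


def make_profile(basal=1.0, silenced=0.5, genes=GENES):
    return ExpressionProfile(
        basal_fc={g: basal for g in genes},
        silenced_fc={g: silenced for g in genes},
    )


@pytest.fixture
def small_cohort():
    """Six complete patients, three per class, with expression."""
    records = [
        make_record(f"p{i}", recurrence=(i >= 3),
                    extracapsular_extension=(i >= 3),
                    pathological_stage_raw="pT3a N0 Mx" if i >= 3 else "pT2c N0 Mx")
        for i in range(6)
    ]
    expr = {r.patient_id: make_profile(1.0 + 0.2 * i, 0.5) for i, r in enumerate(records)}
    return Cohort(records=records, expression=expr)
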
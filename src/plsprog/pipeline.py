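"""End-to-end orchestration: cohort -> features -> PLS-DA -> evaluation.

For each requested criterium the pipeline applies the optional MALAT1
silencing filter, assembles the complete-case feature matrix (listwise
deletion), selects the number of components by leave-one-out Q2, fits the
final model, and evaluates it: permutation p-value for Q2, ROC AUC with a
stratified-bootstrap CI, the Youden threshold with its misclassification
error, component loadings and score-variable correlations. A univariate
group-comparison table (Welch t, Mann-Whitney, Fisher) accompanies the
reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical_features import (
    AdverseFeatureWeights,
    CRITERIA,
    FeatureMatrix,
    InsufficientDataError,
    adverse_clinical_features_score,
    assemble_feature_matrix,
    encode_pathological_stage,
    gleason_to_isup,
)
from .cohort_io import Cohort, read_cohort
from .evaluation import (
    EvaluationReport,
    auc_ci,
    group_compare,
    loo_cv_q2,
    misclassification_error,
    permutation_pvalue,
    roc_auc,
    roc_curve_points,
    youden_threshold,
)
from .expression_features import filter_silenced
from .plsda import component_variable_correlations, fit_plsda, predict_scores
from .simulate import CohortSimParams, generate_cohort

__all__ = ["RunConfig", "run_analysis", "compare_criteria", "evaluate_criterium"]

logger = logging.getLogger("plsprog")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | Path | None = None
    sim_params: CohortSimParams | None = None
    criteria: tuple[str, ...] = ("classical", "new")
    silencing_filter: bool = False
    silencing_threshold: float = 17.0
    max_components: int = 3
    n_permutations: int = 1000
    bootstrap_b: int = 2000
    seed: int = 0
    out_dir: str | Path | None = None
    weights: AdverseFeatureWeights = field(default_factory=AdverseFeatureWeights)

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("at least one criterium is required")
        for c in self.criteria:
            if c not in CRITERIA:
                raise ValueError(f"unknown criterium {c!r}")
        if self.n_permutations < 1 or self.bootstrap_b < 1:
            raise ValueError("permutation and bootstrap counts must be >= 1")
        if self.input_path is None and self.sim_params is None:
            raise ValueError("either input_path or sim_params must be given")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def evaluate_criterium(
    fm: FeatureMatrix,
    criterium: str,
    max_components: int = 3,
    n_permutations: int = 1000,
    bootstrap_b: int = 2000,
    seed: int = 0,
) -> tuple[EvaluationReport, "np.ndarray", tuple]:
    """Fit and evaluate one feature matrix; returns (report, scores, roc points)."""
    rng = np.random.default_rng(seed)
    q2s, selected = loo_cv_q2(fm.values, fm.labels, max_components=max_components)
    perm_p, q2_obs = permutation_pvalue(
        fm.values, fm.labels, B=n_permutations,
        max_components=max_components, seed=rng,
    )
    model = fit_plsda(
        fm.values, fm.labels, n_components=selected, column_names=fm.column_names
    )
    scores = predict_scores(model, fm.values)
    auc = roc_auc(scores, fm.labels)
    ci = auc_ci(scores, fm.labels, B=bootstrap_b, seed=rng)
    thr, sens, spec = youden_threshold(scores, fm.labels)
    err, wrong_ids = misclassification_error(scores, fm.labels, thr, ids=fm.row_ids)
    kept = model.scaling.kept_columns
    loadings = {
        fm.column_names[kept[j]]: float(model.weights[j, 0]) for j in range(len(kept))
    }
    correlations = component_variable_correlations(
        model,
        extra_vars={fm.column_names[kept[j]]: fm.values[:, kept[j]] for j in range(len(kept))},
    )
    report = EvaluationReport(
        criterium=criterium,
        n=fm.n,
        n_recurrent=int(fm.labels.sum()),
        n_components_selected=model.n_components,
        q2=q2_obs,
        q2_per_component=q2s,
        permutation_p=perm_p,
        auc=auc,
        auc_ci=ci,
        youden_threshold=thr,
        sensitivity=sens,
        specificity=spec,
        misclassification_error=err,
        misclassified_ids=wrong_ids,
        explained_x_variance=model.explained_x_variance_.tolist(),
        loadings=loadings,
        correlations=correlations,
        dropped_ids=fm.dropped_ids,
    )
    return report, scores, roc_curve_points(scores, fm.labels)


def _univariate_table(cohort: Cohort) -> pd.DataFrame:
    """Recurrent vs non-recurrent comparisons of the composite variables."""
    rows = []
    rec = np.array([r.recurrence for r in cohort.records], dtype=bool)

    def split(vals):
        v = np.asarray(vals, dtype=float)
        ok = ~np.isnan(v)
        return v[ok & ~rec[: len(v)]], v[ok & rec[: len(v)]]

    quantitative = {
        "age": [float(r.age) for r in cohort.records],
        "serum_psa": [r.serum_psa for r in cohort.records],
        "isup": [float(gleason_to_isup(r.gleason_primary, r.gleason_secondary)) for r in cohort.records],
        "stage_code": [
            float(c) if (c := encode_pathological_stage(r.pathological_stage_raw)) else np.nan
            for r in cohort.records
        ],
        "adverse_score": [
            s if (s := adverse_clinical_features_score(r.adverse_flags)) is not None else np.nan
            for r in cohort.records
        ],
    }
    for name, vals in quantitative.items():
        b, a = split(vals)  # a = recurrent group
        if len(a) < 2 or len(b) < 2:
            continue
        res = group_compare(a, b, kind="quantitative")
        rows.append({"variable": name, **{k: v for k, v in res.items() if k != "kind"}})

    flags = {
        "ece": [r.extracapsular_extension for r in cohort.records],
        "lvi": [r.lymphovascular_invasion for r in cohort.records],
        "margins": [r.surgical_margins_positive for r in cohort.records],
        "pni": [r.perineural_invasion for r in cohort.records],
        "svi": [
            encode_pathological_stage(r.pathological_stage_raw) == 5
            for r in cohort.records
        ],
    }
    for name, vals in flags.items():
        known = [(v, rc) for v, rc in zip(vals, rec) if v is not None]
        a = np.array([float(v) for v, rc in known if rc])
        b = np.array([float(v) for v, rc in known if not rc])
        if len(a) == 0 or len(b) == 0:
            continue
        res = group_compare(a, b, kind="dichotomous")
        rows.append({"variable": name, **{k: v for k, v in res.items() if k != "kind"}})
    return pd.DataFrame(rows)


def _round_sig(x, sig: int = 4):
    if isinstance(x, float):
        if x == 0 or not np.isfinite(x):
            return x
        return float(f"{x:.{sig}g}")
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    return x


def run_analysis(config: RunConfig) -> dict[str, EvaluationReport | Exception]:
    """Run the full pipeline; one report (or error) per requested criterium.

    When ``config.out_dir`` is set, writes per-criterium JSON reports
    (sorted keys, 4 significant digits), ROC coordinate TSVs, the
    univariate comparison table and a run log.
    """
    if config.input_path is not None:
        cohort = read_cohort(config.input_path)
    else:
        cohort = generate_cohort(config.sim_params)
    logger.info(
        "cohort loaded: n=%d (%d recurrent)", len(cohort),
        sum(r.recurrence for r in cohort.records),
    )

    dropped_by_filter: list[str] = []
    if config.silencing_filter:
        cohort, dropped_by_filter = filter_silenced(cohort, config.silencing_threshold)
        logger.info(
            "silencing filter (>=%.0f%% depletion): n=%d retained, %d dropped",
            config.silencing_threshold, len(cohort), len(dropped_by_filter),
        )

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    results: dict[str, EvaluationReport | Exception] = {}
    rng_seeds = {c: config.seed + i for i, c in enumerate(config.criteria)}
    for criterium in config.criteria:
        try:
            fm = assemble_feature_matrix(cohort, criterium, weights=config.weights)
            logger.info(
                "criterium %s: %d/%d complete rows (%d recurrent)",
                criterium, fm.n, len(cohort), int(fm.labels.sum()),
            )
            report, scores, roc = evaluate_criterium(
                fm, criterium,
                max_components=config.max_components,
                n_permutations=config.n_permutations,
                bootstrap_b=config.bootstrap_b,
                seed=rng_seeds[criterium],
            )
        except (InsufficientDataError, ValueError) as exc:
            logger.warning("criterium %s failed: %s", criterium, exc)
            results[criterium] = exc
            continue
        results[criterium] = report
        if out_dir:
            doc = _round_sig(report.to_dict())
            (out_dir / f"report_{criterium}.json").write_text(
                json.dumps(doc, sort_keys=True, indent=1) + "\n"
            )
            fpr, tpr, thr = roc
            pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
                out_dir / f"roc_{criterium}.tsv", sep="\t", index=False
            )

    if out_dir:
        table = _univariate_table(cohort)
        table.to_csv(out_dir / "univariate.tsv", sep="\t", index=False)
        log = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_input": len(cohort) + len(dropped_by_filter),
            "n_after_silencing_filter": len(cohort),
            "dropped_by_silencing_filter": dropped_by_filter,
            "criteria_run": list(config.criteria),
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, sort_keys=True, indent=1) + "\n")
    return results


def compare_criteria(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Tabulate Q2, AUC and error across criteria fitted on the same rows.

    Also reports, per criterium, the misclassified ids not shared with the
    other criteria (symmetric-difference bookkeeping).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    row_sets = {
        c: set(r.misclassified_ids) | set()  # ids are within the same cohort rows
        for c, r in reports.items()
    }
    ns = {r.n for r in reports.values()}
    if len(ns) > 1:
        raise ValueError(f"reports cover different row counts: {sorted(ns)}")
    rows = []
    for c, r in reports.items():
        others = set().union(*(row_sets[o] for o in reports if o != c))
        rows.append(
            {
                "criterium": c,
                "q2": r.q2,
                "auc": r.auc,
                "misclassification_error": r.misclassification_error,
                "n_misclassified": len(r.misclassified_ids),
                "uniquely_misclassified": sorted(set(r.misclassified_ids) - others),
            }
        )
    return pd.DataFrame(rows)
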
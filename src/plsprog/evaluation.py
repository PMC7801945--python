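"""Model evaluation: cross-validated Q2, permutation null, ROC, Youden.

Q2 follows the chemometric convention Q2 = 1 - PRESS/TSS with PRESS
accumulated over leave-one-out predictions and TSS around the full-sample
label mean; Q2 <= 0 means the model predicts no better than the mean. The
permutation p-value re-runs the entire cross-validation on label-shuffled
data, keeping the null exchangeable with the observed statistic, and uses
the add-one estimator (b+1)/(B+1). AUC is the Mann-Whitney pair statistic
(ties count one half); the Youden threshold maximises sensitivity +
specificity - 1 over midpoints of adjacent distinct scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plsda import apply_scaling, fit_plsda

__all__ = [
    "EvaluationReport",
    "ContingencyTable2x2",
    "loo_cv_q2",
    "permutation_pvalue",
    "roc_auc",
    "roc_curve_points",
    "auc_ci",
    "youden_threshold",
    "misclassification_error",
    "fisher_exact_2x2",
    "group_compare",
]


@dataclass
class EvaluationReport:
    """Everything the pipeline reports about one fitted criterium."""

    criterium: str
    n: int
    n_recurrent: int
    n_components_selected: int
    q2: float
    q2_per_component: list[float]
    permutation_p: float
    auc: float
    auc_ci: tuple[float, float]
    youden_threshold: float
    sensitivity: float
    specificity: float
    misclassification_error: float
    misclassified_ids: list[str]
    explained_x_variance: list[float]
    loadings: dict[str, float] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    dropped_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["auc_ci"] = list(self.auc_ci)
        return d


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for outcome (rows: recurrent yes/no) vs a binary feature."""

    a: int  # recurrent, feature positive
    b: int  # recurrent, feature negative
    c: int  # non-recurrent, feature positive
    d: int  # non-recurrent, feature negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _loo_predictions(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Leave-one-out predictions, rescaling and refitting on every fold.

    A training fold that loses one class (or all feature variation) falls
    back to predicting its label mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    preds = np.empty(n)
    warned = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if len(np.unique(y_tr)) < 2:
            if not warned:
                warnings.warn(
                    "a leave-one-out fold lost a class; predicting the fold mean",
                    UserWarning,
                    stacklevel=3,
                )
                warned = True
            preds[i] = y_tr.mean()
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # zero-variance drops in folds
            try:
                model = fit_plsda(X_tr, y_tr, n_components=n_components)
            except ValueError:
                preds[i] = y_tr.mean()
                continue
            Xs = apply_scaling(X[i : i + 1], model.scaling)
        preds[i] = model.y_mean + float((Xs @ model.coefficients)[0])
    return preds


def loo_cv_q2(
    X: np.ndarray, y: np.ndarray, max_components: int = 3
) -> tuple[list[float], int]:
    """Leave-one-out Q2 for 1..max_components components; pick the best.

    Returns (q2 per component count, selected number of components). The
    selected count maximises Q2, so Q2(selected) >= Q2(1) by construction.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 samples for leave-one-out Q2")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    tss = float(((y - y.mean()) ** 2).sum())
    max_components = max(1, min(max_components, n - 2))
    q2s: list[float] = []
    for a in range(1, max_components + 1):
        preds = _loo_predictions(X, y, a)
        press = float(((y - preds) ** 2).sum())
        q2s.append(1.0 - press / tss)
    selected = int(np.argmax(q2s)) + 1
    return q2s, selected


def permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    max_components: int = 3,
    seed: int | np.random.Generator | None = None,
    statistic=None,
) -> tuple[float, float]:
    """Permutation p-value for the cross-validated Q2.

    ``statistic(X, y)`` defaults to the best Q2 from :func:`loo_cv_q2`; the
    full selection procedure is re-run inside every permutation. Returns
    (p, observed Q2) with p = (#{Q2_perm >= Q2_obs} + 1)/(B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if statistic is None:
        def statistic(Xa, ya):
            q2s, sel = loo_cv_q2(Xa, ya, max_components=max_components)
            return q2s[sel - 1]
    y = np.asarray(y, dtype=float).ravel()
    observed = statistic(X, y)
    exceed = 0
    for _ in range(B):
        y_perm = rng.permutation(y)
        if len(np.unique(y_perm)) < 2:  # pragma: no cover - permutation keeps counts
            continue
        if statistic(X, y_perm) >= observed:
            exceed += 1
    return (exceed + 1) / (B + 1), float(observed)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the Mann-Whitney pair statistic.

    Fraction of (positive, negative) pairs where the positive scores
    higher, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) over the candidate threshold grid."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = _candidate_thresholds(scores)
    tpr = np.array([( (scores >= t) & labels).sum() / labels.sum() for t in thresholds])
    fpr = np.array(
        [((scores >= t) & ~labels).sum() / (~labels).sum() for t in thresholds]
    )
    order = np.argsort(fpr, kind="stable")
    return fpr[order], tpr[order], thresholds[order]


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    B: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile interval for the AUC, clipped to [0, 1].

    Resampling is within class, so every replicate keeps both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos, neg = scores[labels], scores[~labels]
    aucs = np.empty(B)
    for b in range(B):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([ps, ns])
        lab = np.concatenate([np.ones(len(ps), bool), np.zeros(len(ns), bool)])
        aucs[b] = roc_auc(s, lab)
    alpha = 1.0 - level
    low, high = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def youden_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores
    plus +-infinity; a sample is called positive when score >= threshold.
    Ties in J are broken toward the smallest maximising threshold. Returns
    (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    best = None
    for t in _candidate_thresholds(scores):
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), float(sens), float(spec)


def misclassification_error(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    ids: list[str] | None = None,
) -> tuple[float, list[str]]:
    """Fraction of samples misclassified at ``threshold``, with their ids."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    wrong = pred != labels
    if ids is None:
        ids = [str(i) for i in range(len(labels))]
    return float(wrong.mean()), [i for i, w in zip(ids, wrong) if w]


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one.
    """
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def group_compare(
    group_a: np.ndarray, group_b: np.ndarray, kind: str = "quantitative"
) -> dict:
    """Compare recurrent vs non-recurrent patients on one variable.

    Quantitative variables get a Welch t-test and a Mann-Whitney U test
    plus group means +- sd and medians with ranges; dichotomous variables
    get a Fisher exact test on the 2x2 positivity table.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "dichotomous":
        table = ContingencyTable2x2(
            a=int(a.sum()), b=int(len(a) - a.sum()),
            c=int(b.sum()), d=int(len(b) - b.sum()),
        )
        return {
            "kind": "dichotomous",
            "rate_a": float(a.mean()),
            "rate_b": float(b.mean()),
            "fisher_p": fisher_exact_2x2(table),
        }
    if len(a) < 2 or len(b) < 2:
        raise ValueError("quantitative tests need >= 2 observations per group")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
    try:
        u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
    except ValueError:  # all values identical
        u_stat, u_p = float("nan"), 1.0
    return {
        "kind": "quantitative",
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "median_a": float(np.median(a)), "range_a": (float(a.min()), float(a.max())),
        "median_b": float(np.median(b)), "range_b": (float(b.min()), float(b.max())),
        "t_stat": float(t_stat), "t_p": float(t_p),
        "u_stat": float(u_stat), "u_p": float(u_p),
    }
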
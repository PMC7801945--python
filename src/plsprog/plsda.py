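"""Partial least-squares discriminant analysis, fitted with NIPALS.

The class indicator (recurrent = 1, non-recurrent = 0) is regressed on
autoscaled features. For a single response NIPALS reduces to, per
component: weight w proportional to X'y (unit norm), score t = Xw,
X-loading p = X't / t't, y-loading q = y't / t't, then deflation of X by
t p'. Y-deflation is omitted — for a univariate response it changes
nothing. The component sign is fixed so the weight entry of largest
magnitude is positive, which makes loadings reproducible across runs.

Predictions are the usual PLS regression form y_hat = y_mean + X_scaled B
with B = W (P'W)^-1 q.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ScalingParams",
    "PLSModel",
    "autoscale",
    "apply_scaling",
    "fit_plsda",
    "predict_scores",
    "explained_x_variance",
    "component_variable_correlations",
]

#: NIPALS inner-loop convergence tolerance on the weight update.
WEIGHT_TOL = 1e-10
MAX_ITER = 500


@dataclass
class ScalingParams:
    """Column means and sample standard deviations (ddof=1) used for autoscaling."""

    column_means: np.ndarray
    column_sds: np.ndarray
    kept_columns: np.ndarray  # indices into the original columns

    def to_dict(self) -> dict:
        return {
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "kept_columns": self.kept_columns.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            column_means=np.asarray(d["column_means"], dtype=float),
            column_sds=np.asarray(d["column_sds"], dtype=float),
            kept_columns=np.asarray(d["kept_columns"], dtype=int),
        )


def autoscale(X: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Centre and scale each column to mean 0, sample sd 1.

    Zero-variance columns carry no discriminative information and break the
    scaling; they are dropped with a warning. Requires n >= 2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscale needs a 2-D matrix with at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sds > 0)
    if keep.size < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - keep.size} zero-variance column(s)",
            UserWarning,
            stacklevel=2,
        )
    params = ScalingParams(
        column_means=means[keep], column_sds=sds[keep], kept_columns=keep
    )
    return (X[:, keep] - means[keep]) / sds[keep], params


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Apply previously estimated scaling to new rows."""
    X = np.asarray(X, dtype=float)
    return (X[:, params.kept_columns] - params.column_means) / params.column_sds


@dataclass
class PLSModel:
    """A fitted PLS-DA model (weights, loadings, scores, scaling)."""

    n_components: int
    weights: np.ndarray  # p_kept x A, unit-norm columns
    x_loadings: np.ndarray  # p_kept x A
    y_loadings: np.ndarray  # A
    scores: np.ndarray  # n x A, training scores
    scaling: ScalingParams
    y_mean: float
    explained_x_variance_: np.ndarray  # A fractions of ||X_scaled||_F^2
    column_names: list[str] | None = None

    @property
    def coefficients(self) -> np.ndarray:
        """Regression vector B in the scaled feature space."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "scaling": self.scaling.to_dict(),
            "y_mean": self.y_mean,
            "explained_x_variance": self.explained_x_variance_.tolist(),
            "column_names": self.column_names,
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            n_components=d["n_components"],
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            scores=np.asarray(d["scores"], dtype=float),
            scaling=ScalingParams.from_dict(d["scaling"]),
            y_mean=d["y_mean"],
            explained_x_variance_=np.asarray(d["explained_x_variance"], dtype=float),
            column_names=d.get("column_names"),
        )


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 1,
    column_names: list[str] | None = None,
) -> PLSModel:
    """Fit a PLS-DA model on raw features ``X`` and binary labels ``y``.

    ``X`` is autoscaled internally; ``y`` is coded 1/0 and centred. If the
    deflated X becomes numerically zero before ``n_components`` components
    are extracted, fitting stops early with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    Xs, scaling = autoscale(X)
    n, p = Xs.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_components = min(n_components, n - 1, p) if p > 0 else 0

    y_mean = float(y.mean())
    yc = y - y_mean
    total_x_var = float((Xs**2).sum())

    Xd = Xs.copy()
    W, P, T, q, evar = [], [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12 * max(1.0, np.abs(Xd).max(initial=0.0)):
            warnings.warn(
                f"deflated X numerically zero; stopping at {len(W)} component(s)",
                UserWarning,
                stacklevel=2,
            )
            break
        w = w / norm
        # inner NIPALS loop; converges in one pass for a univariate response
        # but iterate anyway to keep the algorithm general
        for _ in range(MAX_ITER):
            t = Xd @ w
            q_a = float(yc @ t / (t @ t))
            w_new = Xd.T @ (yc * q_a)
            w_new = w_new / np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < WEIGHT_TOL:
                w = w_new
                break
            w = w_new
        # sign convention: largest-|.| weight entry positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p_load = Xd.T @ t / tt
        q_a = float(yc @ t / tt)
        Xd = Xd - np.outer(t, p_load)
        W.append(w)
        P.append(p_load)
        T.append(t)
        q.append(q_a)
        evar.append(tt * float(p_load @ p_load) / total_x_var)

    if not W:
        raise ValueError("could not extract any component (X has no variation)")
    return PLSModel(
        n_components=len(W),
        weights=np.column_stack(W),
        x_loadings=np.column_stack(P),
        y_loadings=np.asarray(q, dtype=float),
        scores=np.column_stack(T),
        scaling=scaling,
        y_mean=y_mean,
        explained_x_variance_=np.asarray(evar, dtype=float),
        column_names=column_names,
    )


def predict_scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Continuous predicted class values for new rows.

    Applies the training scaling and the PLS regression vector:
    y_hat = y_mean + X_scaled B. A row at the training centroid predicts
    exactly ``y_mean``.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2:
        raise ValueError("X_new must be 2-D")
    if X_new.shape[1] < int(model.scaling.kept_columns.max(initial=-1)) + 1:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model was trained on a wider matrix"
        )
    Xs = apply_scaling(X_new, model.scaling)
    return model.y_mean + Xs @ model.coefficients


def explained_x_variance(model: PLSModel) -> np.ndarray:
    """Fraction of scaled-X variance captured by each component."""
    return model.explained_x_variance_.copy()


def component_variable_correlations(
    model: PLSModel,
    X: np.ndarray | None = None,
    extra_vars: dict[str, np.ndarray] | None = None,
    component: int = 0,
) -> dict[str, float]:
    """Pearson correlation of component scores with each variable.

    ``X`` columns are named from ``model.column_names`` when available.
    Zero-variance variables have no defined correlation and are reported
    as NaN.
    """
    t = model.scores[:, component]
    out: dict[str, float] = {}

    def corr(v: np.ndarray) -> float:
        v = np.asarray(v, dtype=float)
        if v.std() == 0 or t.std() == 0:
            return float("nan")
        return float(np.corrcoef(t, v)[0, 1])

    if X is not None:
        X = np.asarray(X, dtype=float)
        names = model.column_names or [f"x{j}" for j in range(X.shape[1])]
        for j in range(X.shape[1]):
            out[names[j]] = corr(X[:, j])
    for name, v in (extra_vars or {}).items():
        out[name] = corr(v)
    return out
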
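"""Gaussian discriminant classification with noise-injected forward
feature selection.

LDA and QDA model each class as a Gaussian; LDA pools one shared
covariance (linear decision surfaces), QDA keeps per-class covariances
(quadratic surfaces).  Covariances get a relative ridge
``λ · (tr Σ / d) · I`` because night-difference features can be nearly
collinear.  The discriminant score of class ``c`` is

    δ_c(x) = −½ log|Σ_c| − ½ (x − μ_c)ᵀ Σ_c⁻¹ (x − μ_c) + log π_c

with empirical priors π_c.  Feature selection is a greedy sequential
forward search maximizing validation balanced accuracy; to blunt selection
overfitting the training set is doubled with additive Gaussian noise
(per-feature SD scaled) before the search, and the final model is refit on
the clean data restricted to the selected features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from .errors import FitError, ValidationError

#: label preferred on exact score ties (alert logic prefers the quiet class
#: at the observation level; night-level ties are resolved the other way)
TIE_BREAK_LABEL = "non_migraine_comparison"


def balanced_accuracy_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rates = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(rates))


def inject_noise(X: np.ndarray, y: np.ndarray, strength: float,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Double the training set with one noisy copy per observation.

    Noise is ``Normal(0, (strength × per-feature SD)²)`` with labels
    preserved; ``strength = 0`` appends exact copies.
    """
    if strength < 0:
        raise ValidationError("noise strength must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    sd = np.std(X, axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    noisy = X + rng.normal(0.0, 1.0, size=X.shape) * (strength * sd)
    return np.vstack([X, noisy]), np.concatenate([y, y])


@dataclass
class DiscriminantModel:
    """A fitted LDA/QDA classifier."""

    kind: str                      # "lda" | "qda"
    classes: list[str]
    means: np.ndarray              # (C, d)
    covariances: np.ndarray        # (C, d, d); identical slices for lda
    log_priors: np.ndarray         # (C,)
    regularization: float
    selected_features: list[str] = field(default_factory=list)
    # cached factorizations
    _chol: list[np.ndarray] = field(default_factory=list, repr=False)
    _logdet: np.ndarray | None = field(default=None, repr=False)

    def _prepare(self) -> None:
        self._chol, logdets = [], []
        for cov in self.covariances:
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"covariance not positive definite: {exc}") from exc
            self._chol.append(L)
            logdets.append(2.0 * np.sum(np.log(np.diag(L))))
        self._logdet = np.asarray(logdets)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Discriminant scores δ_c(x); shape ``(n, C)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValidationError(
                f"expected {self.means.shape[1]} features, got {X.shape[1]}")
        if not self._chol:
            self._prepare()
        out = np.empty((len(X), len(self.classes)))
        for c in range(len(self.classes)):
            diff = (X - self.means[c]).T
            w = solve_triangular(self._chol[c], diff, lower=True)
            maha = np.sum(w * w, axis=0)
            out[:, c] = -0.5 * self._logdet[c] - 0.5 * maha + self.log_priors[c]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_labels(self, X)

    def to_json(self, path) -> None:
        """Serialize the fitted model (means, covariances, priors, ridge,
        selected features) as documented JSON."""
        payload = {
            "kind": self.kind,
            "classes": self.classes,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "log_priors": self.log_priors.tolist(),
            "regularization": self.regularization,
            "selected_features": self.selected_features,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        p = json.loads(Path(path).read_text())
        return cls(kind=p["kind"], classes=p["classes"],
                   means=np.asarray(p["means"]),
                   covariances=np.asarray(p["covariances"]),
                   log_priors=np.asarray(p["log_priors"]),
                   regularization=p["regularization"],
                   selected_features=list(p["selected_features"]))


def _class_stats(X: np.ndarray, y: np.ndarray, kind: str):
    """Per-class counts, means and covariances (pooled for LDA)."""
    classes = sorted(np.unique(y).tolist(), key=lambda c: (c != TIE_BREAK_LABEL, c))
    if len(classes) < 2:
        raise FitError(f"need >= 2 classes, got {classes}")
    d = X.shape[1]
    means, covs, counts = [], [], []
    for c in classes:
        Xc = X[y == c]
        if len(Xc) < 2:
            raise FitError(f"class {c!r} has {len(Xc)} observations; need >= 2")
        means.append(Xc.mean(axis=0))
        covs.append(np.cov(Xc, rowvar=False, ddof=1).reshape(d, d))
        counts.append(len(Xc))
    counts = np.asarray(counts, dtype=float)
    if kind == "lda":
        pooled = sum((n - 1) * S for n, S in zip(counts, covs)) / (counts.sum() - len(classes))
        covs = [pooled.copy() for _ in classes]
    return classes, np.asarray(means), np.asarray(covs), counts


def _model_from_stats(kind: str, classes: list[str], means: np.ndarray,
                      covs: np.ndarray, counts: np.ndarray, lam: float,
                      selected_features: list[str] | None = None) -> DiscriminantModel:
    d = means.shape[1]
    reg_covs = []
    for S in covs:
        scale = np.trace(S) / d
        if scale <= 0:
            scale = 1.0  # fully degenerate class: fall back to identity ridge
        reg_covs.append(S + lam * scale * np.eye(d))
    model = DiscriminantModel(
        kind=kind, classes=classes, means=means,
        covariances=np.asarray(reg_covs),
        log_priors=np.log(counts / counts.sum()),
        regularization=lam,
        selected_features=list(selected_features or []),
    )
    model._prepare()
    return model


def fit_discriminant(X: np.ndarray, y: np.ndarray, kind: str = "qda",
                     lam: float = 1e-6,
                     selected_features: list[str] | None = None) -> DiscriminantModel:
    """Fit an LDA or QDA model with relative-ridge regularization.

    Requires at least two classes with two observations each.  Classes are
    ordered with the tie-break label first so ties resolve deterministically.
    """
    if kind not in ("lda", "qda"):
        raise ValidationError(f"kind must be 'lda' or 'qda', got {kind!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, means, covs, counts = _class_stats(X, y, kind)
    return _model_from_stats(kind, classes, means, covs, counts, lam,
                             selected_features)


def predict_labels(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the discriminant scores; exact ties go to the first class
    in the model's ordering (the non-migraine comparison when present)."""
    scores = model.scores(X)
    idx = np.argmax(scores, axis=1)  # argmax takes the first maximum: the tie rule
    return np.asarray(model.classes)[idx]


def sfs_select(X_train: np.ndarray, y_train: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray, kind: str = "qda",
               lam: float = 1e-6, eps: float = 1e-3, max_features: int = 15,
               feature_names: list[str] | None = None) -> list[int] | list[str]:
    """Greedy sequential forward selection on validation balanced accuracy.

    At each step the feature whose addition maximizes validation balanced
    accuracy is added; the search stops when the best improvement falls
    below ``eps`` or ``max_features`` is reached.  Even when nothing beats
    the empty model, the single best feature is returned.  Training data
    are expected to be noise-injected by the caller.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValidationError("train and validation sets must be nonempty")
    d = X_train.shape[1]
    # full-dimensional class statistics once; every candidate subset model
    # is an exact submatrix slice of these (identical to refitting on the
    # subset, since sample means/covariances restrict by projection)
    classes, means, covs, counts = _class_stats(X_train, y_train, kind)
    selected: list[int] = []
    best_score = -np.inf
    while len(selected) < min(max_features, d):
        cand_scores = np.full(d, -np.inf)
        for j in range(d):
            if j in selected:
                continue
            cols = selected + [j]
            ix = np.ix_(cols, cols)
            try:
                m = _model_from_stats(kind, classes, means[:, cols],
                                      np.stack([S[ix] for S in covs]),
                                      counts, lam)
            except FitError:
                continue
            cand_scores[j] = balanced_accuracy_score(y_val, predict_labels(m, X_val[:, cols]))
        j_best = int(np.argmax(cand_scores))
        if not np.isfinite(cand_scores[j_best]):
            break
        improvement = cand_scores[j_best] - (best_score if selected else -np.inf)
        if selected and improvement < eps:
            break
        selected.append(j_best)
        best_score = cand_scores[j_best]
    if feature_names is not None:
        return [feature_names[j] for j in selected]
    return selected
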
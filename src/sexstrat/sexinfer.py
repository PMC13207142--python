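"""Expression-based sex inference.

Biological sex is inferred from the logCPM of six sex-chromosome genes —
XIST (X-linked, expressed essentially only in females) and five Y-linked
genes (EIF1AY, KDM5D, UTY, DDX3Y, RPS4Y1, expressed essentially only in
males) — with an L1-penalized logistic regression.  The penalty is chosen by
stratified k-fold cross-validation minimizing mean binomial deviance over a
descending lambda path (glmnet convention: the objective is the mean
negative log-likelihood plus ``lambda * sum(|beta|)`` on standardized
features, intercept unpenalized).  Samples with predicted probability of
being female strictly greater than the threshold (default 0.5) are called
female; everything else, including a tie at exactly 0.5, is called male.

Fitting is coordinate descent on the penalized weighted least-squares
problem of an IRLS (iteratively reweighted least squares) quadratic
approximation, with warm starts along the path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .normalize import logcpm
from .simulate import MARKER_GENES

_PMIN = 1e-5  # probability clip inside IRLS, as in glmnet


def extract_sex_features(counts: pd.DataFrame,
                         marker_ids=MARKER_GENES) -> pd.DataFrame:
    """Per-sample logCPM of the six marker genes (samples x markers).

    Library-size normalization only (no TMM), pseudo-count 0.5; all-zero
    markers therefore stay finite.
    """
    missing = [g for g in marker_ids if g not in counts.index]
    if missing:
        raise ValueError(f"marker genes absent from counts: {missing}")
    # CPM denominators use the full library, not the marker submatrix
    feats = logcpm(counts, factors=None, prior=0.5).loc[list(marker_ids)].T
    if not np.isfinite(feats.to_numpy()).all():
        raise ValueError("non-finite marker features")
    return feats


@dataclass
class SexClassifier:
    """A fitted six-gene sex classifier (female is the positive class)."""

    intercept: float
    coefficients: pd.Series           # keyed by marker gene, fixed order
    lambda_: float
    threshold: float = 0.5
    positive_class: str = "female"

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != list(self.coefficients.index):
            raise ValueError(
                f"feature order mismatch: model expects "
                f"{list(self.coefficients.index)}, got {list(features.columns)}")
        return self.intercept + features.to_numpy(float) @ self.coefficients.to_numpy()

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        eta = self.linear_predictor(features)
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index,
                         name="probability_female")

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-sample probability_female and label (strict > threshold rule)."""
        proba = self.predict_proba(features)
        label = np.where(proba > self.threshold, "female", "male")
        return pd.DataFrame({"probability_female": proba,
                             "sex": label}, index=features.index)

    def to_json(self, path: str) -> None:
        payload = {"intercept": self.intercept,
                   "coefficients": self.coefficients.to_dict(),
                   "feature_order": list(self.coefficients.index),
                   "lambda": self.lambda_, "threshold": self.threshold,
                   "positive_class": self.positive_class}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SexClassifier":
        with open(path) as fh:
            d = json.load(fh)
        coefs = pd.Series({g: d["coefficients"][g] for g in d["feature_order"]})
        return cls(intercept=d["intercept"], coefficients=coefs,
                   lambda_=d["lambda"], threshold=d["threshold"],
                   positive_class=d.get("positive_class", "female"))


@numba.njit(cache=False)
def _cd_lasso_logistic(X, y, lam, beta0, beta,
                       tol=1e-9, max_outer=100, max_inner=1000):
    """Coordinate descent over IRLS approximations on standardized X.

    Minimizes ``mean(-loglik) + lam * sum(|beta|)``; intercept unpenalized.
    ``beta0``/``beta`` are warm starts (modified copies returned).  The
    inner penalized least-squares problem is solved on precomputed Gram
    products, so each sweep is O(p^2) regardless of n.
    """
    n, p = X.shape
    beta = beta.copy()
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        prob = np.minimum(np.maximum(prob, _PMIN), 1.0 - _PMIN)
        w = prob * (1.0 - prob)
        z = eta + (y - prob) / w
        old0 = beta0
        old = beta.copy()
        # Gram products of the weighted problem (augmented with intercept)
        Xw = X * w.reshape(-1, 1)
        G = (Xw.T @ X) / n                    # p x p
        xw_sum = Xw.sum(axis=0) / n           # p, = X' w 1 / n
        w_mean = w.sum() / n
        xz = (Xw.T @ z) / n                   # p
        wz_mean = (w * z).sum() / n
        for _ in range(max_inner):
            delta = 0.0
            # intercept (unpenalized)
            d0 = (wz_mean - xw_sum @ beta) / w_mean - beta0
            beta0 += d0
            delta = max(delta, abs(d0))
            for j in range(p):
                if G[j, j] <= 0.0:
                    continue
                rho = xz[j] - beta0 * xw_sum[j] - G[j] @ beta + G[j, j] * beta[j]
                bj = np.sign(rho) * max(abs(rho) - lam, 0.0) / G[j, j]
                diff = bj - beta[j]
                if diff != 0.0:
                    beta[j] = bj
                    delta = max(delta, abs(diff))
            if delta < tol:
                break
        moved = abs(beta0 - old0)
        for j in range(p):
            moved = max(moved, abs(beta[j] - old[j]))
        if moved < 1e-8:
            break
    return beta0, beta


def lasso_logistic_path(X: np.ndarray, y: np.ndarray,
                        lambdas: np.ndarray):
    """Fit the descending-lambda path on standardized X with warm starts.

    Returns (intercepts, coefficient matrix ``len(lambdas) x p``).
    """
    n, p = X.shape
    b0 = float(np.log(y.mean() / (1.0 - y.mean())))
    beta = np.zeros(p)
    b0s = np.empty(len(lambdas))
    betas = np.empty((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        b0, beta = _cd_lasso_logistic(X, y, lam, b0, beta)
        b0s[i] = b0
        betas[i] = beta
    return b0s, betas


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                        ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced descending grid from lambda_max (all coefficients zero)."""
    ybar = y.mean()
    lam_max = np.max(np.abs(X.T @ (y - ybar))) / len(y)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    prob = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def fit_lasso_logistic(features: pd.DataFrame, labels,
                       lambda_grid: np.ndarray | None = None,
                       n_folds: int = 10, seed: int = 0,
                       threshold: float = 0.5) -> "SexClassifierResults":
    """Cross-validated LASSO logistic fit of sex on marker features.

    ``labels`` are 'female'/'male' strings (female coded 1).  Features are
    standardized internally for penalization and the fit is reported on the
    original scale.  Deterministic given ``seed`` (which fixes the fold
    assignment).
    """
    labels = pd.Series(np.asarray(labels), index=features.index)
    bad = set(labels) - {"male", "female"}
    if bad:
        raise ValueError(f"labels must be 'male'/'female', got {sorted(bad)}")
    y = (labels == "female").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")
    X_raw = features.to_numpy(float)
    if not np.isfinite(X_raw).all():
        raise ValueError("non-finite feature values")
    n, p = X_raw.shape
    n_min = int(min(y.sum(), n - y.sum()))
    if n_min < 2:
        raise ValueError("need at least 2 samples per class")
    n_folds = int(n_folds)
    if n_folds > n_min:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class size {n_min}")

    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)          # population SD, glmnet convention
    sd = np.where(sd > 0, sd, 1.0)
    X = (X_raw - mu) / sd

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, float)
    order = np.argsort(lambda_grid)[::-1]
    lambda_grid = lambda_grid[order]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_dev = np.zeros((n_folds, len(lambda_grid)))
    for k, (tr, va) in enumerate(skf.split(X, y)):
        b0s, betas = lasso_logistic_path(X[tr], y[tr], lambda_grid)
        for i in range(len(lambda_grid)):
            eta = b0s[i] + X[va] @ betas[i]
            cv_dev[k, i] = _binomial_deviance(y[va], eta)
    mean_dev = cv_dev.mean(axis=0)
    best = int(np.argmin(mean_dev))   # ties resolve to the larger lambda
    lam = float(lambda_grid[best])

    b0s, betas = lasso_logistic_path(X, y, lambda_grid[:best + 1])
    b0_std, beta_std = b0s[-1], betas[-1]
    coef = beta_std / sd
    intercept = float(b0_std - np.sum(beta_std * mu / sd))

    classifier = SexClassifier(
        intercept=intercept,
        coefficients=pd.Series(coef, index=features.columns),
        lambda_=lam, threshold=threshold)
    cv_table = pd.DataFrame({"lambda": lambda_grid, "mean_cv_deviance": mean_dev,
                             "se_cv_deviance": cv_dev.std(axis=0, ddof=1)
                             / np.sqrt(n_folds)})
    return SexClassifierResults(classifier=classifier, cv_table=cv_table,
                                n_obs=n, n_folds=n_folds, seed=seed,
                                feature_names=list(features.columns))


class SexInferenceModel:
    """Model object for six-marker sex inference (fit -> results pattern).

    Parameters
    ----------
    features : samples x markers logCPM table (see :func:`extract_sex_features`).
    labels : per-sample 'male'/'female' training labels, aligned to features.
    """

    def __init__(self, features: pd.DataFrame, labels):
        self.features = features
        self.labels = pd.Series(np.asarray(labels), index=features.index)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, meta: pd.DataFrame,
                    marker_ids=MARKER_GENES) -> "SexInferenceModel":
        """Build from a count matrix and metadata with reported sex.

        Only samples with reported (non-unknown) sex enter training.
        """
        known = meta[meta["sex"].isin(["male", "female"])]
        if known.empty:
            raise ValueError("no samples with reported sex to train on")
        feats = extract_sex_features(counts[known["sample_id"]], marker_ids)
        return cls(feats, known.set_index("sample_id").loc[feats.index, "sex"])

    def fit(self, lambda_grid=None, n_folds: int = 10, seed: int = 0,
            threshold: float = 0.5) -> "SexClassifierResults":
        return fit_lasso_logistic(self.features, self.labels,
                                  lambda_grid=lambda_grid, n_folds=n_folds,
                                  seed=seed, threshold=threshold)


@dataclass
class ClassifierReport:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def evaluate_classifier(predicted, true_labels) -> ClassifierReport:
    """Confusion-matrix metrics with female as the positive class."""
    predicted = np.asarray(predicted)
    true_labels = np.asarray(true_labels)
    if predicted.shape != true_labels.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs "
            f"{true_labels.shape} truths")
    pos_p = predicted == "female"
    pos_t = true_labels == "female"
    return ClassifierReport(tp=int((pos_p & pos_t).sum()),
                            tn=int((~pos_p & ~pos_t).sum()),
                            fp=int((pos_p & ~pos_t).sum()),
                            fn=int((~pos_p & pos_t).sum()))


@dataclass
class SexClassifierResults:
    """Results of a cross-validated LASSO logistic sex-classifier fit."""

    classifier: SexClassifier
    cv_table: pd.DataFrame
    n_obs: int
    n_folds: int
    seed: int
    feature_names: list[str] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return pd.concat([pd.Series({"intercept": self.classifier.intercept}),
                          self.classifier.coefficients])

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.classifier.predict(features)

    def evaluate(self, features: pd.DataFrame, true_labels) -> ClassifierReport:
        pred = self.predict(features)["sex"]
        return evaluate_classifier(pred.to_numpy(), np.asarray(true_labels))

    def summary(self) -> str:
        c = self.classifier
        lines = ["Six-marker LASSO logistic sex classifier",
                 "=" * 44,
                 f"n obs: {self.n_obs}   CV folds: {self.n_folds}   "
                 f"seed: {self.seed}",
                 f"chosen lambda: {c.lambda_:.6g}   threshold: {c.threshold}"
                 f"   positive class: {c.positive_class}",
                 "-" * 44,
                 f"{'term':<12}{'coef':>12}",
                 f"{'intercept':<12}{c.intercept:>12.4f}"]
        for g, b in c.coefficients.items():
            lines.append(f"{g:<12}{b:>12.4f}")
        return "\n".join(lines)


def infer_missing_sex(counts: pd.DataFrame, meta: pd.DataFrame,
                      model: SexClassifier | SexClassifierResults,
                      marker_ids=MARKER_GENES) -> pd.DataFrame:
    """Fill ``unknown`` sex from the classifier; reported labels never change.

    Adds a ``sex_source`` column ('reported' or 'inferred').
    """
    if isinstance(model, SexClassifierResults):
        model = model.classifier
    meta = meta.copy()
    if "sex_source" not in meta.columns:
        meta["sex_source"] = np.where(meta["sex"] == "unknown", "unknown",
                                      "reported")
    unknown = meta["sex"] == "unknown"
    if not unknown.any():
        return meta
    ids = meta.loc[unknown, "sample_id"].tolist()
    feats = extract_sex_features(counts[ids], marker_ids)
    pred = model.predict(feats)
    meta.loc[unknown, "sex"] = pred.loc[ids, "sex"].to_numpy()
    meta.loc[unknown, "sex_source"] = "inferred"
    return meta
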
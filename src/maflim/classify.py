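"""Pixel-level tissue classification and image-level scoring.

Four classical models (LDA, QDA, linear SVM with C = 100, logistic
regression) are trained on per-pixel feature vectors; every valid pixel
inherits its image's histopathology label (lesion image → positive,
contralateral healthy → negative), an explicit label-noise assumption
since only image-level ground truth exists.

Applying a trained model to an image yields a posterior probability map
P(dysplasia/cancer | pixel).  The whole image is summarized by a
Brier-like score — the mean of the squared pixel posteriors — and
classified positive when that score reaches a threshold chosen on the
training ROC as the point of maximum sensitivity subject to
(1 − specificity) ≤ 30%.

An SVM–QDA ensemble combines a spectral-feature member and a
time-resolved-feature member by a convex combination
``w1·p_svm + (1 − w1)·p_qda`` of their posterior maps.

scikit-learn performs the underlying fits; the fitted parameters are
extracted into a plain, JSON-serializable form and posteriors are
evaluated from those parameters, so a reloaded model reproduces its
predictions bit-for-bit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .core import ConfigError, MaflimError, ValidationError
from .features import FEATURE_NAMES, FeatureStack

MODEL_KINDS = ("LDA", "QDA", "SVM", "LOGREG")


class TrainingError(MaflimError, ValueError):
    """Training is impossible on the given data (e.g. one class only)."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainedPixelModel:
    """A fitted pixel classifier with calibrated posteriors.

    ``params`` holds the extracted model parameters:

    * linear kinds (LDA, LOGREG): ``coef`` (d,), ``intercept`` —
      posterior = sigmoid(coef·z + intercept) on standardized features z;
    * SVM: additionally ``platt_a``, ``platt_b`` — posterior =
      sigmoid(a·f + b) of the margin f = coef·z + intercept;
    * QDA: ``priors`` (2,), ``means`` (2, d), ``covs`` (2, d, d) —
      posterior by the two-class Gaussian discriminant.
    """

    model_kind: str
    selected_features: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    params: dict
    image_score_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind {self.model_kind!r}")
        self.selected_features = tuple(self.selected_features)
        if not (1 <= len(self.selected_features) <= 3):
            raise ValidationError("selected_features must have size 1-3")
        unknown = set(self.selected_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValidationError(f"features outside the inventory: {sorted(unknown)}")
        if self.image_score_threshold is not None and not (
            0 <= self.image_score_threshold <= 1
        ):
            raise ValidationError("image_score_threshold must lie in [0, 1]")
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=float)

    # -- prediction ---------------------------------------------------------

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior P(positive) for feature rows X (unstandardized)."""
        Z = self.standardize(np.asarray(X, dtype=float))
        if self.model_kind in ("LDA", "LOGREG"):
            f = Z @ np.asarray(self.params["coef"]) + self.params["intercept"]
            return _sigmoid(f)
        if self.model_kind == "SVM":
            f = Z @ np.asarray(self.params["coef"]) + self.params["intercept"]
            return _sigmoid(self.params["platt_a"] * f + self.params["platt_b"])
        # QDA
        priors = np.asarray(self.params["priors"])
        means = np.asarray(self.params["means"])
        covs = np.asarray(self.params["covs"])
        logp = np.empty((Z.shape[0], 2))
        for k in range(2):
            diff = Z - means[k]
            cov = covs[k]
            sign, logdet = np.linalg.slogdet(cov)
            sol = np.linalg.solve(cov, diff.T).T
            maha = np.einsum("ij,ij->i", diff, sol)
            logp[:, k] = np.log(priors[k]) - 0.5 * (logdet + maha)
        return _sigmoid(logp[:, 1] - logp[:, 0])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return {
            "model_kind": self.model_kind,
            "selected_features": list(self.selected_features),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "params": params,
            "image_score_threshold": self.image_score_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedPixelModel":
        params = {
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in d["params"].items()
        }
        return cls(
            model_kind=d["model_kind"],
            selected_features=tuple(d["selected_features"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            params=params,
            image_score_threshold=d.get("image_score_threshold"),
        )

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedPixelModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def _regularize_cov(cov: np.ndarray) -> np.ndarray:
    """Add a 1e-6 trace-scaled ridge when the covariance is near-singular."""
    d = cov.shape[0]
    scale = np.trace(cov) / d
    if scale <= 0:
        scale = 1.0
    eig_min = np.linalg.eigvalsh(cov)[0]
    if eig_min < 1e-9 * scale:
        warnings.warn("near-singular class covariance; adding trace-scaled ridge")
        cov = cov + 1e-6 * scale * np.eye(d)
    return cov


def train_pixel_classifier(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str,
    feature_names: Sequence[str],
) -> TrainedPixelModel:
    """Fit one pixel classifier on labeled feature vectors.

    Features are z-scored with training statistics (stored on the model
    and re-applied at prediction).  Deterministic given the data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("X must be (n_samples, n_features) matching y")
    if len(feature_names) != X.shape[1]:
        raise ValidationError("feature_names length must match X columns")
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("training needs both classes present")
    if model_kind not in MODEL_KINDS:
        raise ValidationError(f"unknown model kind {model_kind!r}")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale

    if model_kind == "LDA":
        est = LinearDiscriminantAnalysis()
        est.fit(Z, y)
        params = {"coef": est.coef_[0].copy(), "intercept": float(est.intercept_[0])}
    elif model_kind == "QDA":
        try:
            est = QuadraticDiscriminantAnalysis(store_covariance=True)
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message="Variables are collinear")
                est.fit(Z, y)
            priors, means, covs_raw = est.priors_, est.means_, est.covariance_
        except np.linalg.LinAlgError:
            # rank-deficient class covariance: take the empirical moments
            # directly; the ridge below restores invertibility
            d = Z.shape[1]
            priors = np.array([(y == k).mean() for k in (0, 1)])
            means = np.vstack([Z[y == k].mean(axis=0) for k in (0, 1)])
            covs_raw = [np.cov(Z[y == k].T, ddof=1).reshape(d, d) for k in (0, 1)]
        covs = np.stack([_regularize_cov(np.asarray(c)) for c in covs_raw])
        params = {
            "priors": np.asarray(priors).copy(),
            "means": np.asarray(means).copy(),
            "covs": covs,
        }
    elif model_kind == "SVM":
        est = LinearSVC(C=100.0, dual=False)  # L2-regularized, squared hinge
        est.fit(Z, y)
        f = est.decision_function(Z)
        platt = LogisticRegression(C=np.inf, max_iter=1000)
        platt.fit(f[:, None], y)
        params = {
            "coef": est.coef_[0].copy(),
            "intercept": float(est.intercept_[0]),
            "platt_a": float(platt.coef_[0, 0]),
            "platt_b": float(platt.intercept_[0]),
        }
    else:  # LOGREG: (effectively) unpenalized maximum likelihood
        est = LogisticRegression(C=np.inf, max_iter=1000)
        est.fit(Z, y)
        params = {"coef": est.coef_[0].copy(), "intercept": float(est.intercept_[0])}

    return TrainedPixelModel(
        model_kind=model_kind,
        selected_features=tuple(feature_names),
        scaler_mean=mean,
        scaler_scale=scale,
        params=params,
    )


@dataclass
class ProbabilityMap:
    """Posterior P(dysplasia/cancer) per valid pixel; NaN elsewhere."""

    p: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.valid.shape:
            raise ValidationError("probability map / mask shape mismatch")
        vals = self.p[self.valid]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValidationError("posteriors must lie in [0, 1]")

    @property
    def values(self) -> np.ndarray:
        return self.p[self.valid]


def posterior_map(model: TrainedPixelModel, stack: FeatureStack) -> ProbabilityMap:
    """Apply a trained model to every valid pixel of a feature stack."""
    X = stack.submatrix(model.selected_features)
    p = np.full(stack.valid.shape, np.nan)
    if X.shape[0]:
        p[stack.valid] = model.predict_proba(X)
    return ProbabilityMap(p=p, valid=stack.valid.copy())


def image_score(pmap: ProbabilityMap) -> float:
    """Brier-like image score: mean of squared pixel posteriors."""
    vals = pmap.values
    if vals.size == 0:
        raise ValidationError("image score undefined on an empty map")
    return float(np.mean(vals**2))


def optimize_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    max_fpr: float = 0.30,
) -> float:
    """Pick the image-score threshold of maximum sensitivity subject to
    (1 − specificity) ≤ ``max_fpr``.

    Candidates are the midpoints between sorted unique scores plus
    sentinels below the minimum and above the maximum.  Ties are broken
    by lower FPR, then by the higher threshold.  If no feasible
    threshold classifies any positive correctly, the feasible threshold
    is still returned and a warning is emitted.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise TrainingError("threshold optimization needs both classes")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1.0]]
    )
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best: tuple[float, float, float] | None = None  # (sens, -fpr, thr)
    for thr in candidates:
        pred = s >= thr
        sens = float(np.sum(pred & (y == 1))) / n_pos
        fpr = float(np.sum(pred & (y == 0))) / n_neg
        if fpr > max_fpr:
            continue
        key = (sens, -fpr, thr)
        if best is None or key > best:
            best = key
    assert best is not None  # thr above max is always feasible (fpr = 0)
    if best[0] == 0:
        warnings.warn("no feasible threshold achieves sensitivity > 0")
    return float(best[2])


def classify_image(score: float, threshold: float) -> int:
    """Positive (1) iff the image score reaches the threshold (inclusive)."""
    return int(score >= threshold)


def ensemble_posterior(
    map_a: ProbabilityMap, map_b: ProbabilityMap, w1: float
) -> ProbabilityMap:
    """Convex combination ``w1·p_a + (1 − w1)·p_b`` of two posterior maps
    over identical valid masks."""
    if not (0 <= w1 <= 1):
        raise ConfigError(f"w1 must lie in [0, 1], got {w1}")
    if not np.array_equal(map_a.valid, map_b.valid):
        raise ValidationError("ensemble members have different valid masks")
    p = np.full(map_a.p.shape, np.nan)
    p[map_a.valid] = w1 * map_a.p[map_a.valid] + (1 - w1) * map_b.p[map_b.valid]
    return ProbabilityMap(p=p, valid=map_a.valid.copy())


@dataclass
class EnsembleModel:
    """Weighted-posterior ensemble of a spectral and a time-resolved member."""

    model_a: TrainedPixelModel
    model_b: TrainedPixelModel
    w1: float
    image_score_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.w1 <= 1):
            raise ValidationError(f"w1 must lie in [0, 1], got {self.w1}")
        if set(self.model_a.selected_features) & set(self.model_b.selected_features):
            raise ValidationError("ensemble members must use disjoint feature pools")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    def posterior(self, stack: FeatureStack) -> ProbabilityMap:
        return ensemble_posterior(
            posterior_map(self.model_a, stack),
            posterior_map(self.model_b, stack),
            self.w1,
        )

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a.to_dict(),
            "model_b": self.model_b.to_dict(),
            "w1": self.w1,
            "image_score_threshold": self.image_score_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            model_a=TrainedPixelModel.from_dict(d["model_a"]),
            model_b=TrainedPixelModel.from_dict(d["model_b"]),
            w1=d["w1"],
            image_score_threshold=d.get("image_score_threshold"),
        )

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))
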
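"""Feature selection and cross-validated model optimization.

The cohort design is paired: each subject contributes a lesion image and
a contralateral healthy image, and the pair always travels together —
folds partition subjects, never images.  For 34 subjects and k = 7 the
fold sizes are six folds of 5 subjects (10 images) and one of 4
(8 images).

Per cross-validation fold, a sequential forward search (SFS) grows a
feature set of size ≤ 3 from one pool (spectral-only or
time-resolved-only), adding at each step the feature that maximizes the
training-fold image-level ROC-AUC; the final set is the greedy prefix
with the largest AUC (ties favor the smaller set).  The image-score
threshold is optimized on the training folds only; standardization
statistics likewise.  Pooled validation predictions over all folds give
one confusion matrix.

The SVM–QDA ensemble is optimized by repeating the full k-fold CV for
every weight w1 ∈ {0, 0.1, …, 1} with both members retrained per fold on
their fixed top-3 feature sets (no further feature selection), choosing
the w1 that maximizes F1 (ties: higher sensitivity, then lower w1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import (
    EnsembleModel,
    TrainedPixelModel,
    TrainingError,
    classify_image,
    ensemble_posterior,
    image_score,
    optimize_threshold,
    posterior_map,
    train_pixel_classifier,
)
from .core import ConfigError, Dataset, MaflimImage
from .features import FEATURE_NAMES, FeatureStack, build_feature_stack
from .fitting import FitConfig, fit_image
from .metrics import ConfusionMatrix, confusion, roc_auc
from .preprocess import PreprocessConfig, preprocess
from .simulate import SyntheticScene


@dataclass
class ImageRecord:
    """One image reduced to its per-pixel feature stack plus labels."""

    image_id: str
    subject_id: str
    label: int  # 1 = dysplasia/cancer, 0 = healthy
    grade: str
    stack: FeatureStack


def compute_image_features(
    image: MaflimImage,
    irf,
    pre_cfg: PreprocessConfig | None = None,
    fit_cfg: FitConfig | None = None,
    manual_regions: list[dict] | None = None,
) -> FeatureStack:
    """Full single-image pipeline: preprocess → fit → 21-feature stack."""
    processed, mask = preprocess(image, pre_cfg, manual_regions)
    fits = fit_image(processed, irf, mask, fit_cfg)
    return build_feature_stack(processed, fits, mask)


def dataset_records(
    dataset: Dataset,
    scenes: dict[str, SyntheticScene] | None = None,
    irf=None,
    pre_cfg: PreprocessConfig | None = None,
    fit_cfg: FitConfig | None = None,
) -> list[ImageRecord]:
    """Run the feature pipeline over a paired dataset.

    The per-image IRF comes from ``scenes`` (synthetic cohorts) or the
    shared ``irf`` argument.
    """
    records = []
    for subj in dataset:
        for kind, img, label in (
            ("healthy", subj.healthy, 0),
            ("lesion", subj.lesion, 1),
        ):
            image_id = f"{subj.subject_id}:{kind}"
            the_irf = scenes[image_id].irf if scenes is not None else irf
            stack = compute_image_features(img, the_irf, pre_cfg, fit_cfg)
            records.append(
                ImageRecord(
                    image_id=image_id,
                    subject_id=subj.subject_id,
                    label=label,
                    grade=subj.grade if label == 1 else "Healthy",
                    stack=stack,
                )
            )
    return records


@dataclass
class FoldPlan:
    """Partition of subjects into k folds; pairs never split."""

    folds: list[list[int]]

    def __post_init__(self) -> None:
        flat = [i for f in self.folds for i in f]
        if len(set(flat)) != len(flat):
            raise ConfigError("folds overlap")

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(n_subjects: int, k: int = 7, seed: int = 0) -> FoldPlan:
    """Shuffle subjects by seed, assign round-robin: fold sizes as equal
    as possible (34 subjects, k=7 → six folds of 5 and one of 4)."""
    if n_subjects < k:
        raise ConfigError(f"fewer subjects ({n_subjects}) than folds ({k})")
    order = np.random.default_rng(seed).permutation(n_subjects)
    folds: list[list[int]] = [[] for _ in range(k)]
    for pos, subj in enumerate(order):
        folds[pos % k].append(int(subj))
    return FoldPlan(folds=folds)


def _pixel_training_data(
    records: list[ImageRecord], features: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([r.stack.submatrix(features) for r in records])
    y = np.concatenate([np.full(r.stack.n_valid, r.label) for r in records])
    return X, y


def _train_and_score(
    train: list[ImageRecord], model_kind: str, features: list[str]
) -> tuple[TrainedPixelModel, np.ndarray]:
    """Train on pooled training pixels; return model + training image scores."""
    X, y = _pixel_training_data(train, features)
    model = train_pixel_classifier(X, y, model_kind, features)
    scores = np.array([image_score(posterior_map(model, r.stack)) for r in train])
    return model, scores


def sequential_forward_search(
    train: list[ImageRecord],
    model_kind: str,
    feature_pool: list[str] | tuple[str, ...],
    max_features: int = 3,
) -> tuple[list[str], list[float]]:
    """Greedy SFS on training images.

    Returns the selected feature set (the greedy-path prefix with the
    largest training image-level ROC-AUC; ties prefer the smaller set)
    and the AUC at each path length.  Candidate ties at a step are
    broken by canonical inventory order (the pool is kept in that order).
    """
    pool = [f for f in FEATURE_NAMES if f in set(feature_pool)]
    if not pool:
        raise ConfigError("empty feature pool")
    labels = np.array([r.label for r in train])
    selected: list[str] = []
    auc_path: list[float] = []
    remaining = list(pool)
    while remaining and len(selected) < max_features:
        best_feat, best_auc = None, -np.inf
        for feat in remaining:
            _, scores = _train_and_score(train, model_kind, selected + [feat])
            auc = roc_auc(scores, labels)
            if auc > best_auc:
                best_feat, best_auc = feat, auc
        selected.append(best_feat)
        remaining.remove(best_feat)
        auc_path.append(best_auc)
    best_len = int(np.argmax(auc_path)) + 1  # argmax takes the first → smaller set
    return selected[:best_len], auc_path


@dataclass
class SelectionTrace:
    """Per-fold SFS outcomes and the cross-fold feature-frequency table."""

    fold_features: list[list[str]]
    fold_auc_paths: list[list[float]]

    @property
    def frequency(self) -> dict[str, int]:
        freq: dict[str, int] = {}
        for feats in self.fold_features:
            for f in feats:
                freq[f] = freq.get(f, 0) + 1
        return freq

    def top_features(self, n: int = 3) -> list[str]:
        """The n most frequently selected features (ties: canonical order)."""
        freq = self.frequency
        ranked = sorted(
            freq, key=lambda f: (-freq[f], FEATURE_NAMES.index(f))
        )
        return ranked[:n]


@dataclass
class CVResult:
    """Pooled 7-fold cross-validation outcome."""

    confusion: ConfusionMatrix
    trace: SelectionTrace
    image_ids: list[str]
    scores: list[float]
    labels: list[int]
    predictions: list[int]
    grades: list[str]
    fold_provenance: list[dict] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return roc_auc(self.scores, self.labels)


def cross_validate(
    records: list[ImageRecord],
    model_kind: str,
    feature_pool: list[str] | tuple[str, ...],
    k: int = 7,
    seed: int = 0,
    max_features: int = 3,
) -> CVResult:
    """Paired k-fold CV with per-fold SFS and threshold optimization.

    All training-fold-only statistics (standardization, SFS choices,
    thresholds) are recorded in ``fold_provenance`` together with the
    image ids they touched, so leakage is checkable after the fact.
    """
    subjects = sorted({r.subject_id for r in records})
    by_subject = {s: [r for r in records if r.subject_id == s] for s in subjects}
    plan = make_folds(len(subjects), k=k, seed=seed)

    fold_features, fold_paths, provenance = [], [], []
    ids, scores, labels, preds, grades = [], [], [], [], []
    for fold_idx, fold in enumerate(plan.folds):
        val_subj = {subjects[i] for i in fold}
        train = [r for s in subjects if s not in val_subj for r in by_subject[s]]
        val = [r for s in sorted(val_subj) for r in by_subject[s]]
        train_labels = {r.label for r in train}
        if len(train_labels) < 2:
            warnings.warn(f"fold {fold_idx}: single-class training set; skipped")
            continue
        feats, path = sequential_forward_search(
            train, model_kind, feature_pool, max_features
        )
        model, train_scores = _train_and_score(train, model_kind, feats)
        thr = optimize_threshold(train_scores, [r.label for r in train])
        model.image_score_threshold = thr
        fold_features.append(feats)
        fold_paths.append(path)
        provenance.append(
            {
                "fold": fold_idx,
                "train_images": [r.image_id for r in train],
                "val_images": [r.image_id for r in val],
                "features": feats,
                "threshold": thr,
            }
        )
        for r in val:
            s = image_score(posterior_map(model, r.stack))
            ids.append(r.image_id)
            scores.append(s)
            labels.append(r.label)
            preds.append(classify_image(s, thr))
            grades.append(r.grade)

    cm = confusion(preds, labels, grades)
    return CVResult(
        confusion=cm,
        trace=SelectionTrace(fold_features=fold_features, fold_auc_paths=fold_paths),
        image_ids=ids,
        scores=scores,
        labels=labels,
        predictions=preds,
        grades=grades,
        fold_provenance=provenance,
    )


def _ensemble_fold_predictions(
    records: list[ImageRecord],
    spectral: tuple[str, list[str]],
    time_resolved: tuple[str, list[str]],
    w1: float,
    plan: FoldPlan,
    subjects: list[str],
    by_subject: dict[str, list[ImageRecord]],
) -> tuple[list[int], list[int], list[float], list[str]]:
    preds, labels, scores, grades = [], [], [], []
    for fold in plan.folds:
        val_subj = {subjects[i] for i in fold}
        train = [r for s in subjects if s not in val_subj for r in by_subject[s]]
        val = [r for s in sorted(val_subj) for r in by_subject[s]]
        kind_a, feats_a = spectral
        kind_b, feats_b = time_resolved
        Xa, y = _pixel_training_data(train, feats_a)
        Xb, _ = _pixel_training_data(train, feats_b)
        model_a = train_pixel_classifier(Xa, y, kind_a, feats_a)
        model_b = train_pixel_classifier(Xb, y, kind_b, feats_b)

        def weighted_score(r: ImageRecord) -> float:
            pm = ensemble_posterior(
                posterior_map(model_a, r.stack), posterior_map(model_b, r.stack), w1
            )
            return image_score(pm)

        train_scores = np.array([weighted_score(r) for r in train])
        thr = optimize_threshold(train_scores, [r.label for r in train])
        for r in val:
            s = weighted_score(r)
            preds.append(classify_image(s, thr))
            labels.append(r.label)
            scores.append(s)
            grades.append(r.grade)
    return preds, labels, scores, grades


def optimize_ensemble_weight(
    records: list[ImageRecord],
    spectral: tuple[str, list[str]],
    time_resolved: tuple[str, list[str]],
    k: int = 7,
    seed: int = 0,
) -> tuple[float, list[dict]]:
    """Grid-search the ensemble weight w1 over {0, 0.1, …, 1}.

    ``spectral`` / ``time_resolved`` are (model_kind, fixed feature set)
    pairs — the previously identified optimal members with their top-3
    most frequent features; no further feature selection happens here.
    Each candidate w1 gets a full k-fold CV with members retrained per
    fold.  Returns the F1-maximizing w1 (ties: higher sensitivity, then
    lower w1) and the per-weight metric rows.
    """
    from .metrics import f1 as f1_of, sensitivity as sens_of, specificity as spec_of

    subjects = sorted({r.subject_id for r in records})
    by_subject = {s: [r for r in records if r.subject_id == s] for s in subjects}
    plan = make_folds(len(subjects), k=k, seed=seed)
    rows = []
    for w1 in [round(0.1 * i, 1) for i in range(11)]:
        preds, labels, scores, grades = _ensemble_fold_predictions(
            records, spectral, time_resolved, w1, plan, subjects, by_subject
        )
        cm = confusion(preds, labels)
        try:
            row_f1 = f1_of(cm)
        except ZeroDivisionError:
            row_f1 = 0.0
        rows.append(
            {
                "w1": w1,
                "f1": row_f1,
                "sensitivity": sens_of(cm),
                "specificity": spec_of(cm),
                "auc": roc_auc(scores, labels),
                "confusion": cm,
            }
        )
    best = max(rows, key=lambda r: (r["f1"], r["sensitivity"], -r["w1"]))
    return best["w1"], rows


def lock_final_models(
    records: list[ImageRecord],
    spectral: tuple[str, list[str]],
    time_resolved: tuple[str, list[str]],
    w1: float,
) -> tuple[TrainedPixelModel, TrainedPixelModel, EnsembleModel]:
    """Retrain both members and the ensemble on the full training set,
    optimize all thresholds there, and return the locked models."""
    kind_a, feats_a = spectral
    kind_b, feats_b = time_resolved
    Xa, y = _pixel_training_data(records, feats_a)
    Xb, _ = _pixel_training_data(records, feats_b)
    model_a = train_pixel_classifier(Xa, y, kind_a, feats_a)
    model_b = train_pixel_classifier(Xb, y, kind_b, feats_b)
    labels = [r.label for r in records]

    scores_a = [image_score(posterior_map(model_a, r.stack)) for r in records]
    scores_b = [image_score(posterior_map(model_b, r.stack)) for r in records]
    model_a.image_score_threshold = optimize_threshold(scores_a, labels)
    model_b.image_score_threshold = optimize_threshold(scores_b, labels)

    ens = EnsembleModel(model_a=model_a, model_b=model_b, w1=w1)
    scores_e = [image_score(ens.posterior(r.stack)) for r in records]
    ens.image_score_threshold = optimize_threshold(scores_e, labels)
    return model_a, model_b, ens
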
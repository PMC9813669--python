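"""Binary MACE prediction from latent shape features.

A ridge-regularized logistic regression predicts the rare MACE outcome from
per-subject latent posterior means (or from the clinical ES-volume baseline)
under stratified k-fold cross-validation, scored by AUROC.  Features are
standardized per fold on the training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, DegenerateFitError
from .mesh_core import MeshDataset, enclosed_volume
from .mesh_vae import MeshVAEModel, encode_dataset

#: Inverse ridge strength for the logistic fits (sklearn's C); documented default.
DEFAULT_C = 1.0


@dataclass
class ClassificationResult:
    feature_set: str  # "latent" | "es_volume" | caller-defined
    fold_auroc: np.ndarray
    n_folds: int
    seed: int

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def sd_auroc(self) -> float:
        return float(np.std(self.fold_auroc, ddof=1)) if len(self.fold_auroc) > 1 else 0.0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, "auroc": a} for i, a in enumerate(self.fold_auroc)]
        rows.append({"fold": "mean", "auroc": self.mean_auroc})
        rows.append({"fold": "sd", "auroc": self.sd_auroc})
        return pd.DataFrame(rows)


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC by the rank/concordance formula, counting ties as 1/2.

    Equals the probability that a random positive outscores a random
    negative (Mann-Whitney U / (n_pos * n_neg)).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateFitError("AUROC undefined with a single class")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    regularization_c: float = DEFAULT_C,
    seed: int = 0,
) -> LogisticRegression:
    """Ridge-penalized maximum-likelihood logistic fit (deterministic)."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[0] != len(labels):
        features = features.T
    if not np.isfinite(features).all():
        raise ConfigurationError("features must be finite")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateFitError("logistic fit needs both classes present")
    clf = LogisticRegression(C=regularization_c, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit(features, labels)
    return clf


def stratified_cv_auroc(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    feature_set: str = "latent",
    regularization_c: float = DEFAULT_C,
) -> ClassificationResult:
    """Out-of-fold AUROC of a logistic model under stratified k-fold CV.

    Folds preserve class prevalence within one case.  If some fold would
    receive no positive case, k is reduced (with a warning) until each fold
    holds at least one.  Feature standardization is fit on the training
    folds only.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 1:
        features = features[:, None]
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == len(labels):
        raise DegenerateFitError("cross-validation needs both classes")
    if k > n_pos:
        warnings.warn(f"reducing k from {k} to {n_pos} so each fold holds a positive case")
        k = n_pos
    if k < 2:
        raise ConfigurationError("need at least 2 folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_scores = []
    for train_idx, test_idx in skf.split(features, labels):
        scaler = StandardScaler().fit(features[train_idx])
        clf = fit_logistic(scaler.transform(features[train_idx]), labels[train_idx], regularization_c, seed)
        test_x = scaler.transform(features[test_idx])
        if len(np.unique(labels[test_idx])) < 2:
            continue  # AUROC undefined on this fold
        scores = clf.predict_proba(test_x)[:, 1]
        fold_scores.append(auroc(labels[test_idx], scores))
    if not fold_scores:
        raise DegenerateFitError("no fold had both classes in its test set")
    return ClassificationResult(
        feature_set=feature_set, fold_auroc=np.asarray(fold_scores), n_folds=k, seed=seed
    )


def latent_features(model: MeshVAEModel, dataset: MeshDataset) -> np.ndarray:
    """Posterior-mean latent features, one row per subject."""
    return encode_dataset(model, dataset)


def es_volume_baseline(dataset: MeshDataset) -> np.ndarray:
    """Clinical baseline feature: per-subject ES endocardial volume (mL),
    in dataset subject order."""
    return np.array([enclosed_volume(m, "endocardial") for m in dataset.meshes])
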
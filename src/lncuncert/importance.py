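"""Per-fold random forests with additive probability-space attributions.

One RandomForestClassifier is trained per cross-validation fold on the
representative features; each fold's strict held-out transcripts are then
explained with tree-path Shapley values computed on the model's coding
probability, so that for every transcript

    baseline + sum_i phi_i = predicted coding probability  (within 1e-6).

Per-feature mean |phi| pooled over all out-of-fold transcripts gives the
global importance ranking, with the standard deviation of per-fold means as
a stability estimate.  A t-SNE embedding of the feature space is provided
for visual inspection of class/entropy structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import roc_curve

from .treeshap import forest_shap_values
from .uncertainty import CODING

__all__ = ["ForestConfig", "train_forests", "explain", "TranscriptExplanation",
           "top_k_view", "summarize_importance", "embed_2d"]


@dataclass
class ForestConfig:
    n_trees: int = 500
    max_features_rule: str = "sqrt"      # sqrt | log2 | all
    min_leaf: int = 1
    max_depth: int | None = None
    seed: int = 0
    decision_threshold: float = 0.5
    recalibrate_threshold: bool = False  # Youden-J on the training fold

    def validate(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_rule not in ("sqrt", "log2", "all"):
            raise ValueError("max_features_rule must be sqrt, log2 or all")
        return self


@dataclass
class FoldModel:
    fold_index: int
    model: RandomForestClassifier
    feature_names: list
    train_ids: list
    threshold: float


def _fit_one(X, y, config, seed):
    mf = {"sqrt": "sqrt", "log2": "log2", "all": None}[config.max_features_rule]
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, max_features=mf,
        min_samples_leaf=config.min_leaf, max_depth=config.max_depth,
        random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def train_forests(features: pd.DataFrame, labels, folds, config: ForestConfig):
    """One seeded forest per fold, trained on that fold's training ids.

    ``labels`` is a Series of class labels indexed like ``features``;
    the positive class is ``coding``.
    """
    config.validate()
    if not isinstance(labels, pd.Series):
        labels = pd.Series(np.asarray(labels), index=features.index)
    models = []
    for split in folds:
        train_ids = [t for ids in split.train_ids_by_class.values()
                     for t in ids]
        missing = [t for t in train_ids if t not in features.index]
        if missing:
            raise KeyError(f"fold {split.fold_index}: transcripts missing "
                           f"from feature table, e.g. {missing[:5]}")
        X = features.loc[train_ids]
        y = (labels.loc[train_ids] == CODING).astype(int)
        rf = _fit_one(X.to_numpy(dtype=float), y.to_numpy(), config,
                      config.seed + split.fold_index)
        thr = config.decision_threshold
        if config.recalibrate_threshold:
            p = rf.predict_proba(X.to_numpy(dtype=float))[:, 1]
            fpr, tpr, cand = roc_curve(y, p)
            thr = float(cand[np.argmax(tpr - fpr)])
        models.append(FoldModel(split.fold_index, rf,
                                list(features.columns), train_ids, thr))
    return models


@dataclass
class TranscriptExplanation:
    transcript_id: str
    baseline: float
    contributions: pd.Series     # per-feature phi, probability units
    prediction: float

    def check_additivity(self, tol=1e-6):
        return abs(self.baseline + self.contributions.sum()
                   - self.prediction) <= tol


def explain(fold_model: FoldModel, features: pd.DataFrame):
    """Tree-path additive attributions for each row of ``features``.

    Returns (explanations list, phi DataFrame, baseline).  Raises on a
    feature-schema mismatch with the training table.
    """
    if list(features.columns) != fold_model.feature_names:
        raise ValueError("feature columns do not match the training schema")
    X = features.to_numpy(dtype=float)
    phi, baseline = forest_shap_values(fold_model.model, X)
    pred = fold_model.model.predict_proba(X)[:, 1]
    phi_df = pd.DataFrame(phi, index=features.index,
                          columns=features.columns)
    explanations = [
        TranscriptExplanation(tx, baseline, phi_df.loc[tx], float(p))
        for tx, p in zip(features.index, pred)
    ]
    return explanations, phi_df, baseline


def top_k_view(explanation: TranscriptExplanation, k=10):
    """Top-k |phi| features plus one aggregated remainder term."""
    contrib = explanation.contributions
    order = contrib.abs().sort_values(ascending=False).index
    top = contrib.loc[order[:k]]
    remainder = float(contrib.loc[order[k:]].sum())
    view = top.to_dict()
    view["all_other_features"] = remainder
    return view


def summarize_importance(phi_by_fold):
    """Global importance from per-fold out-of-fold attribution tables.

    ``phi_by_fold`` is a list of DataFrames (transcripts x features).
    Mean |phi| is computed over the pooled transcripts; the s.d. is across
    the per-fold means.  Rank 1 is the most important feature.
    """
    if not phi_by_fold:
        raise ValueError("at least one fold required")
    pooled = pd.concat(phi_by_fold, axis=0)
    mean_abs = pooled.abs().mean(axis=0)
    fold_means = pd.DataFrame({i: df.abs().mean(axis=0)
                               for i, df in enumerate(phi_by_fold)})
    sd = fold_means.std(axis=1, ddof=0) if len(phi_by_fold) > 1 else \
        pd.Series(0.0, index=mean_abs.index)
    out = pd.DataFrame({"mean_abs_shap": mean_abs, "sd_across_folds": sd})
    out = out.sort_values("mean_abs_shap", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "feature"
    return out


def embed_2d(features, perplexity=30.0, n_iter=1000, seed=0):
    """Deterministic 2-D t-SNE embedding of the feature space."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} rows for perplexity "
            f"{perplexity}; lower the perplexity")
    tsne = TSNE(n_components=2, perplexity=perplexity, max_iter=n_iter,
                random_state=seed, init="pca")
    return tsne.fit_transform(X)
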
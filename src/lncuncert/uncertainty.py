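"""Ensemble uncertainty decomposition, stratification and agreement analysis.

An ensemble of M coding-potential classifiers emits, for each transcript, a
coding probability p_m in [0, 1].  Uncertainty is decomposed as

    H_pred = H(p_bar)                  predictive entropy of the ensemble mean
    H_exp  = mean_m H(p_m)             expected entropy of the members
    I_dis  = H_pred - H_exp            mutual-information disagreement score

with H the binary Shannon entropy in bits.  I_dis >= 0 by concavity of H; it
is 0 when all members emit the same probability and maximal (1 bit) when
confident members split evenly between the classes.

Transcripts are stratified per reference class: "low" uncertainty below the
10th percentile of H_pred, "high" above the 90th percentiles of both H_pred
and I_dis (strict inequalities, linear-interpolation percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from sklearn.metrics import confusion_matrix

CODING = "coding"
LNCRNA = "lncRNA"
CLASSES = (CODING, LNCRNA)

__all__ = [
    "binary_entropy", "orient_scores", "ensemble_profile", "exclude_incomplete",
    "StratificationThresholds", "compute_thresholds", "stratify",
    "agreement_category", "MetricsReport", "evaluate",
    "prob_columns", "label_columns",
]


def binary_entropy(p):
    """Binary Shannon entropy in bits, with the 0*log2(0) := 0 convention.

    Accepts scalars or arrays; raises ``ValueError`` outside [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("probabilities must be finite and within [0, 1]")
    h = -(xlogy(arr, arr) + xlogy(1.0 - arr, 1.0 - arr)) / np.log(2.0)
    h = h + 0.0  # normalize -0.0 at the extremes
    return float(h) if np.isscalar(p) else h


def orient_scores(raw_score, positive_class=CODING, tool_threshold=0.5,
                  tool="", transcript=""):
    """Orient a tool's raw score to a coding probability and label.

    Tools whose positive class is lncRNA have their score (and threshold)
    inverted.  The label is coding iff p_coding >= oriented threshold
    (ties go to coding; documented convention).
    """
    arr = np.asarray(raw_score, dtype=float)
    bad = ~np.isfinite(arr) | (arr < 0) | (arr > 1)
    if np.any(bad):
        idx = np.argwhere(bad).ravel()[0] if arr.ndim else ""
        raise ValueError(
            f"score outside [0, 1] for tool {tool!r}, transcript "
            f"{transcript or idx!r}")
    if positive_class == CODING:
        p = arr
        thr = tool_threshold
    elif positive_class == LNCRNA:
        p = 1.0 - arr
        thr = 1.0 - tool_threshold
    else:
        raise ValueError(f"unknown positive class {positive_class!r}")
    label = np.where(p >= thr, CODING, LNCRNA)
    if np.isscalar(raw_score):
        return float(p), str(label)
    return p, label


def ensemble_profile(p_tools):
    """Entropy decomposition for an (n, M) matrix of coding probabilities.

    Returns a DataFrame with columns p_mean, H_pred, H_exp, I_dis.
    """
    P = np.asarray(p_tools, dtype=float)
    if P.ndim == 1:
        P = P[None, :]
    if P.shape[1] < 2:
        raise ValueError("an ensemble needs at least 2 tools")
    if np.isnan(P).any():
        raise ValueError("missing tool probabilities; run exclude_incomplete first")
    p_mean = P.mean(axis=1)
    h_pred = binary_entropy(p_mean)
    h_exp = binary_entropy(P).mean(axis=1)
    return pd.DataFrame({
        "p_mean": p_mean,
        "H_pred": h_pred,
        "H_exp": h_exp,
        "I_dis": h_pred - h_exp,
    })


def prob_columns(df):
    return [c for c in df.columns if c.startswith("prob_")]


def label_columns(df):
    return [c for c in df.columns if c.startswith("label_")]


def exclude_incomplete(predictions: pd.DataFrame):
    """Drop transcripts missing any tool probability.

    Returns (complete subset, report) where the report gives the number of
    excluded transcripts and per-tool missingness counts.
    """
    cols = prob_columns(predictions)
    missing = predictions[cols].isna()
    keep = ~missing.any(axis=1)
    report = {
        "n_total": int(len(predictions)),
        "n_excluded": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "missing_per_tool": {c.removeprefix("prob_"): int(missing[c].sum())
                             for c in cols},
    }
    return predictions.loc[keep].copy(), report


@dataclass
class StratificationThresholds:
    """Per-class percentile thresholds for the entropy stratification."""

    per_class: dict = field(default_factory=dict)
    # per_class[class] = {"q10_Hpred": ., "q90_Hpred": ., "q90_Idis": .}
    quantile_convention: str = "linear interpolation over order statistics"
    q_low: float = 0.10
    q_high: float = 0.90


def compute_thresholds(profiles: pd.DataFrame, labels, q_low=0.10,
                       q_high=0.90, classes=CLASSES):
    """Per-class percentiles of H_pred (q_low, q_high) and I_dis (q_high).

    Linear interpolation over order statistics: the q-th percentile sits at
    fractional index q*(N-1) of the sorted values.  ``classes`` lists the
    reference classes the population must contain (both, by default).
    """
    labels = pd.Series(np.asarray(labels), index=profiles.index)
    out = StratificationThresholds(q_low=q_low, q_high=q_high)
    for cls in classes:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"reference class {cls!r} absent")
        h = profiles.loc[mask, "H_pred"].to_numpy()
        i = profiles.loc[mask, "I_dis"].to_numpy()
        out.per_class[cls] = {
            "q10_Hpred": float(np.quantile(h, q_low, method="linear")),
            "q90_Hpred": float(np.quantile(h, q_high, method="linear")),
            "q90_Idis": float(np.quantile(i, q_high, method="linear")),
        }
    return out


def stratify(profiles: pd.DataFrame, labels, thresholds: StratificationThresholds):
    """Assign each transcript to {low, high, intermediate} (strict inequalities)."""
    labels = pd.Series(np.asarray(labels), index=profiles.index)
    group = pd.Series("intermediate", index=profiles.index, dtype=object)
    for cls, t in thresholds.per_class.items():
        m = labels == cls
        low = m & (profiles["H_pred"] < t["q10_Hpred"])
        high = (m & (profiles["H_pred"] > t["q90_Hpred"])
                & (profiles["I_dis"] > t["q90_Idis"]))
        group[low] = "low"
        group[high] = "high"
    return group


def agreement_category(tool_labels, reference, tool_names=None):
    """Categorize inter-tool agreement against the reference label.

    ``tool_labels``: (n, M) array of class labels; ``reference``: length-n.
    Returns a DataFrame with n_correct, category (unanimous_correct /
    unanimous_incorrect / discordant), near_consensus (M-1 or M-2 correct)
    and the pattern of tools voting coding (for upset-style summaries).
    """
    L = np.asarray(tool_labels)
    ref = np.asarray(reference)
    n, M = L.shape
    correct = (L == ref[:, None])
    n_correct = correct.sum(axis=1)
    category = np.where(n_correct == M, "unanimous_correct",
                        np.where(n_correct == 0, "unanimous_incorrect",
                                 "discordant"))
    near = (n_correct >= M - 2) & (n_correct <= M - 1)
    if tool_names is None:
        tool_names = [f"tool{m}" for m in range(M)]
    pattern = ["|".join(t for t, lab in zip(tool_names, row) if lab == CODING)
               for row in L]
    return pd.DataFrame({
        "n_correct": n_correct,
        "category": category,
        "near_consensus": near,
        "pattern": pattern,
    })


@dataclass
class MetricsReport:
    balanced_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: dict
    zero_predicted_classes: list

    def as_dict(self):
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion,
            "zero_predicted_classes": self.zero_predicted_classes,
        }


def evaluate(pred_labels, reference):
    """Macro-averaged classification metrics over the two transcript classes.

    Balanced accuracy is the mean of per-class recalls; precision for a class
    with zero predicted positives is defined as 0 and flagged.
    """
    pred = np.asarray(pred_labels)
    ref = np.asarray(reference)
    classes = list(CLASSES)
    if set(np.unique(ref)) != set(classes):
        raise ValueError("both reference classes must be present")
    cm = confusion_matrix(ref, pred, labels=classes)
    precisions, recalls, f1s, flagged = [], [], [], []
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        pred_pos = cm[:, i].sum()
        actual = cm[i, :].sum()
        if pred_pos == 0:
            flagged.append(cls)
            prec = 0.0
        else:
            prec = tp / pred_pos
        rec = tp / actual
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    confusion = {f"{t}->{p}": int(cm[i, j])
                 for i, t in enumerate(classes) for j, p in enumerate(classes)}
    return MetricsReport(
        balanced_accuracy=float(np.mean(recalls)),
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        confusion=confusion,
        zero_predicted_classes=flagged,
    )
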
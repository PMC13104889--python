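"""Feature preprocessing, redundancy clustering and univariate enrichment.

Continuous features are clustered on a Spearman-correlation-derived distance
d = 1 - |rho| with Ward linkage; the cut height is chosen by maximising the
mean silhouette over a grid of thresholds, and one representative feature is
kept per cluster (highest |effect|, or seeded random).  Group comparisons use
the Mann-Whitney U test with the centered Vargha-Delaney A effect size
(cVDA = A - 0.5) for continuous features, and the chi-squared test with
Cramer's V and odds ratios for categoricals, with Benjamini-Hochberg
correction within each comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency, mannwhitneyu, rankdata, spearmanr
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess", "FeatureClustering", "cluster_features",
    "select_representatives", "vda", "mannwhitney_vda", "chisq_cramers",
    "bh_adjust", "run_enrichment",
]


def preprocess(table: pd.DataFrame, kinds: dict):
    """Split a feature table into continuous and one-hot indicator blocks.

    ``kinds`` maps feature name -> "continuous" | "categorical".  Constant
    and all-missing features are removed and reported.  Categoricals are
    expanded to one indicator per level (no reference level dropped).
    """
    drop_report = {}
    cont_cols, cat_cols = [], []
    for col in table.columns:
        kind = kinds.get(col)
        if kind is None:
            raise KeyError(f"feature {col!r} has no declared kind")
        s = table[col]
        if s.isna().all():
            drop_report[col] = "all missing"
            continue
        if s.nunique(dropna=True) <= 1:
            drop_report[col] = "constant"
            continue
        (cont_cols if kind == "continuous" else cat_cols).append(col)
    continuous = table[cont_cols].copy()
    if cat_cols:
        indicators = pd.get_dummies(table[cat_cols].astype("category"),
                                    prefix_sep="=", dtype=int)
    else:
        indicators = pd.DataFrame(index=table.index)
    return continuous, indicators, drop_report


@dataclass
class FeatureClustering:
    linkage_matrix: np.ndarray
    features: list
    threshold_grid: np.ndarray
    silhouettes: np.ndarray          # NaN where a cut was invalid
    chosen_threshold: float
    cluster_of: dict                 # feature -> cluster id (1-based)
    n_clusters: int
    representatives: dict = field(default_factory=dict)  # cluster id -> feature

    def members(self, cluster_id):
        return [f for f, c in self.cluster_of.items() if c == cluster_id]


def cluster_features(continuous: pd.DataFrame, n_grid: int = 25):
    """Ward clustering of features on d = 1 - |spearman rho|.

    The cut threshold maximising the mean silhouette (computed on d, over
    cuts yielding 2..n-1 clusters) is chosen; ties go to fewer clusters.
    With fewer than 3 features a single cluster is returned.
    """
    feats = list(continuous.columns)
    p = len(feats)
    if p < 3:
        cluster_of = {f: 1 for f in feats}
        return FeatureClustering(np.empty((0, 4)), feats, np.array([]),
                                 np.array([]), np.nan, cluster_of, 1)
    rho = spearmanr(continuous.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - np.abs(rho)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="ward")
    heights = Z[:, 2]
    grid = np.linspace(heights.min(), heights.max(), n_grid)
    sils = np.full(n_grid, np.nan)
    labelings = {}
    for i, t in enumerate(grid):
        lab = fcluster(Z, t=t, criterion="distance")
        k = lab.max()
        labelings[i] = lab
        if 2 <= k <= p - 1:
            sils[i] = silhouette_score(d, lab, metric="precomputed")
    if np.isnan(sils).all():
        best = 0
        lab = labelings[0]
    else:
        top = np.nanmax(sils)
        # ties broken toward fewer clusters
        cand = [i for i in range(n_grid) if not np.isnan(sils[i])
                and np.isclose(sils[i], top)]
        best = min(cand, key=lambda i: (labelings[i].max(), i))
        lab = labelings[best]
    cluster_of = {f: int(c) for f, c in zip(feats, lab)}
    return FeatureClustering(Z, feats, grid, sils, float(grid[best]),
                             cluster_of, int(lab.max()))


def select_representatives(clustering: FeatureClustering, mode="max_effect",
                           effect_fn=None, forced=(), seed=None):
    """Pick one representative feature per cluster.

    Forced features win their cluster unconditionally (e.g. transcript
    length, kept for its established relevance).  Otherwise ``max_effect``
    picks the feature with the largest |effect_fn(feature)| (ties:
    lexicographically smallest name) and ``random`` draws uniformly with the
    given seed.
    """
    if mode == "max_effect" and effect_fn is None:
        raise ValueError("mode='max_effect' requires effect_fn")
    forced = list(forced)
    forced_cluster = {}
    for f in forced:
        c = clustering.cluster_of.get(f)
        if c is None:
            raise KeyError(f"forced feature {f!r} not in clustering")
        if c in forced_cluster:
            raise ValueError(
                f"two forced features ({forced_cluster[c]!r}, {f!r}) "
                f"share cluster {c}")
        forced_cluster[c] = f
    rng = np.random.default_rng(seed)
    reps = {}
    for c in range(1, clustering.n_clusters + 1):
        if c in forced_cluster:
            reps[c] = forced_cluster[c]
            continue
        members = sorted(clustering.members(c))
        if len(members) == 1:
            reps[c] = members[0]
        elif mode == "max_effect":
            best = max(abs(effect_fn(f)) for f in members)
            # ties -> lexicographically smallest name
            tied = [f for f in members if abs(effect_fn(f)) == best]
            reps[c] = sorted(tied)[0]
        elif mode == "random":
            reps[c] = members[int(rng.integers(len(members)))]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    clustering.representatives = reps
    return set(reps.values())


def vda(x, y):
    """Vargha-Delaney A: P(X > Y) + 0.5 P(X = Y), via the rank-sum identity."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    rx = ranks[:nx].sum()
    return (rx - nx * (nx + 1) / 2.0) / (nx * ny)


def mannwhitney_vda(x, y):
    """Mann-Whitney U with the centered Vargha-Delaney effect size.

    Returns (U, two-sided p, cVDA).  p is exact (enumeration) when
    n_x * n_y <= 400 and the data are tie-free, otherwise by normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    small = x.size * y.size <= 400
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if small and not ties else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    a = vda(x, y)
    return float(res.statistic), float(res.pvalue), float(a - 0.5)


def chisq_cramers(table):
    """Chi-squared independence test with Cramer's V (and OR for 2x2 tables).

    No continuity correction.  The odds ratio uses the Haldane +0.5
    adjustment on all cells when any cell is zero.  Returns
    (chi2, p, V, OR-or-None).
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must hold nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    if min(t.shape) < 2:
        raise ValueError("contingency table needs at least 2 rows and columns")
    chi2, p, _, _ = chi2_contingency(t, correction=False)
    n = t.sum()
    r, c = t.shape
    v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    odds = None
    if t.shape == (2, 2):
        tt = t + 0.5 if (t == 0).any() else t
        odds = float(tt[0, 0] * tt[1, 1] / (tt[0, 1] * tt[1, 0]))
    return float(chi2), float(p), v, odds


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(features: pd.DataFrame, kinds: dict, comparisons: dict,
                   alpha=0.01, effect_threshold=0.1):
    """Univariate tests for each feature across each two-group comparison.

    ``comparisons`` maps a comparison name to a pair (index_a, index_b) of
    row labels of ``features``.  Continuous features get Mann-Whitney + cVDA
    (direction: sign of cVDA, positive = higher in group a); categoricals
    (including 0/1 indicators) get chi-squared + Cramer's V + OR (2x2).
    BH correction is applied within each comparison; ``significant`` means
    p_adj < alpha and ``non_negligible`` |cVDA| (or V) > effect_threshold.
    Groups with fewer than 2 members are skipped and reported in the
    "skipped" attribute of the result.
    """
    rows = []
    skipped = []
    for comp, (ia, ib) in comparisons.items():
        a = features.loc[ia]
        b = features.loc[ib]
        if len(a) < 2 or len(b) < 2:
            skipped.append(comp)
            continue
        for col in features.columns:
            kind = kinds.get(col, "continuous")
            try:
                if kind == "continuous":
                    u, p, cvda = mannwhitney_vda(a[col].dropna(),
                                                 b[col].dropna())
                    rows.append(dict(feature=col, comparison=comp,
                                     test="mann_whitney", statistic=u,
                                     p_raw=p, effect=cvda, odds_ratio=np.nan,
                                     direction="a" if cvda > 0 else
                                     ("b" if cvda < 0 else "none")))
                else:
                    levels = sorted(pd.concat([a[col], b[col]]).dropna()
                                    .unique().tolist())
                    tab = np.array([
                        [(a[col] == lv).sum() for lv in levels],
                        [(b[col] == lv).sum() for lv in levels]])
                    chi2, p, v, odds = chisq_cramers(tab)
                    if odds is not None:
                        direction = "a" if odds > 1 else ("b" if odds < 1
                                                          else "none")
                    else:
                        direction = "none"
                    rows.append(dict(feature=col, comparison=comp,
                                     test="chi_squared", statistic=chi2,
                                     p_raw=p, effect=v,
                                     odds_ratio=np.nan if odds is None
                                     else odds,
                                     direction=direction))
            except ValueError:
                continue
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = np.nan
        for comp in out["comparison"].unique():
            m = out["comparison"] == comp
            out.loc[m, "p_adj"] = bh_adjust(out.loc[m, "p_raw"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
        out["non_negligible"] = out["effect"].abs() > effect_threshold
    out.attrs["skipped"] = skipped
    return out
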
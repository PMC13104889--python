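"""Forest training, probability-space attribution and global importance."""

import numpy as np
import pandas as pd
import pytest

from lncuncert.cohort import make_fold_splits
from lncuncert.importance import (ForestConfig, embed_2d, explain,
                                  summarize_importance, top_k_view,
                                  train_forests)
from lncuncert.uncertainty import CODING, LNCRNA, evaluate


def make_dataset(rng, n=400, p=6, informative=0, noise=0.0):
    # noiseless default: the informative feature separates the classes
    X = rng.normal(size=(n, p))
    y = np.where(X[:, informative] + rng.normal(0, noise, n) > 0,
                 CODING, LNCRNA)
    ids = [f"t{i}" for i in range(n)]
    feats = pd.DataFrame(X, index=ids,
                         columns=[f"f{j}" for j in range(p)])
    labels = pd.Series(y, index=ids)
    ids_by_class = {CODING: [t for t in ids if labels[t] == CODING],
                    LNCRNA: [t for t in ids if labels[t] == LNCRNA]}
    folds = make_fold_splits(ids_by_class, k=3, seed=0)
    return feats, labels, folds


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(1)
    feats, labels, folds = make_dataset(rng)
    config = ForestConfig(n_trees=100, seed=0)
    models = train_forests(feats, labels, folds, config)
    return feats, labels, folds, models


class TestTraining:
    def test_separable_problem_near_perfect(self, trained):
        feats, labels, folds, models = trained
        held = [t for v in folds[0].heldout_ids_by_class.values() for t in v]
        pred = models[0].model.predict_proba(
            feats.loc[held].to_numpy(float))[:, 1]
        lab = np.where(pred >= 0.5, CODING, LNCRNA)
        assert evaluate(lab, labels.loc[held]).balanced_accuracy > 0.9

    def test_permuted_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            feats, labels, folds = make_dataset(rng, n=300)
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            ids_by_class = {
                c: list(perm.index[perm == c]) for c in (CODING, LNCRNA)}
            folds = make_fold_splits(ids_by_class, k=3, seed=seed)
            models = train_forests(feats, perm, folds,
                                   ForestConfig(n_trees=60, seed=seed))
            held = [t for v in folds[0].heldout_ids_by_class.values()
                    for t in v]
            p = models[0].model.predict_proba(
                feats.loc[held].to_numpy(float))[:, 1]
            lab = np.where(p >= 0.5, CODING, LNCRNA)
            accs.append(evaluate(lab, perm.loc[held]).balanced_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        feats, labels, folds = make_dataset(rng)
        cfgs = ForestConfig(n_trees=40, seed=7)
        m1 = train_forests(feats, labels, folds, cfgs)
        m2 = train_forests(feats, labels, folds, cfgs)
        X = feats.to_numpy(float)
        np.testing.assert_array_equal(m1[0].model.predict_proba(X),
                                      m2[0].model.predict_proba(X))

    def test_missing_transcripts_reported(self, trained):
        feats, labels, folds, _ = trained
        with pytest.raises(KeyError):
            train_forests(feats.iloc[:10], labels, folds,
                          ForestConfig(n_trees=5))


class TestExplain:
    def test_additivity_for_every_transcript(self, trained):
        feats, labels, folds, models = trained
        held = [t for v in folds[0].heldout_ids_by_class.values() for t in v]
        expl, phi, baseline = explain(models[0], feats.loc[held])
        for e in expl:
            assert e.check_additivity(tol=1e-6)

    def test_schema_mismatch_rejected(self, trained):
        feats, _, _, models = trained
        with pytest.raises(ValueError):
            explain(models[0], feats[list(feats.columns[::-1])])

    def test_informative_feature_dominates(self, trained):
        feats, labels, folds, models = trained
        held = [t for v in folds[0].heldout_ids_by_class.values() for t in v]
        _, phi, _ = explain(models[0], feats.loc[held])
        dominant = (phi["f0"].abs().to_numpy()[:, None]
                    > phi[[f"f{j}" for j in range(1, 6)]].abs().to_numpy())
        assert dominant.all(axis=1).mean() >= 0.99

    def test_top_k_view_sums_to_prediction(self, trained):
        feats, _, folds, models = trained
        held = [t for v in folds[0].heldout_ids_by_class.values() for t in v]
        expl, _, _ = explain(models[0], feats.loc[held][:5])
        for e in expl:
            view = top_k_view(e, k=3)
            assert len(view) == 4  # 3 features + aggregated remainder
            assert e.baseline + sum(view.values()) == \
                pytest.approx(e.prediction, abs=1e-9)


class TestSummary:
    def test_single_fold_sd_zero(self, trained):
        feats, _, folds, models = trained
        held = [t for v in folds[0].heldout_ids_by_class.values() for t in v]
        _, phi, _ = explain(models[0], feats.loc[held])
        summary = summarize_importance([phi])
        assert (summary["sd_across_folds"] == 0).all()
        assert sorted(summary["rank"]) == list(range(1, 7))

    def test_graded_effects_recover_rank_order(self):
        rng = np.random.default_rng(9)
        n = 900
        X = rng.normal(size=(n, 5))
        logit = 2.0 * X[:, 0] + 1.0 * X[:, 1] + 0.5 * X[:, 2]
        y = np.where(logit + rng.normal(0, 0.5, n) > 0, CODING, LNCRNA)
        ids = [f"t{i}" for i in range(n)]
        feats = pd.DataFrame(X, index=ids,
                             columns=[f"f{j}" for j in range(5)])
        labels = pd.Series(y, index=ids)
        ids_by_class = {c: list(labels.index[labels == c])
                        for c in (CODING, LNCRNA)}
        folds = make_fold_splits(ids_by_class, k=3, seed=1)
        models = train_forests(feats, labels, folds,
                               ForestConfig(n_trees=120, seed=1))
        phis = []
        for s, m in zip(folds, models):
            held = [t for v in s.heldout_ids_by_class.values() for t in v]
            _, phi, _ = explain(m, feats.loc[held])
            phis.append(phi)
        summary = summarize_importance(phis)
        assert list(summary.index[:3]) == ["f0", "f1", "f2"]
        # pure-noise features well below the top informative one
        noise = summary.loc[["f3", "f4"], "mean_abs_shap"].max()
        assert summary.loc["f0", "mean_abs_shap"] >= 5 * noise


class TestEmbedding:
    def test_shape_and_determinism(self, rng):
        X = rng.normal(size=(120, 8))
        a = embed_2d(X, perplexity=10, n_iter=300, seed=0)
        b = embed_2d(X, perplexity=10, n_iter=300, seed=0)
        assert a.shape == (120, 2)
        np.testing.assert_array_equal(a, b)

    def test_two_blobs_separate(self, rng):
        X = np.r_[rng.normal(0, 1, size=(100, 6)),
                  rng.normal(8, 1, size=(100, 6))]
        emb = embed_2d(X, perplexity=15, n_iter=400, seed=0)
        c1, c2 = emb[:100].mean(axis=0), emb[100:].mean(axis=0)
        spread = max(emb[:100].std(), emb[100:].std())
        assert np.linalg.norm(c1 - c2) > spread

    def test_too_few_rows_suggests_lower_perplexity(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(rng.normal(size=(20, 4)), perplexity=30)
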
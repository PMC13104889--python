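"""Entropy decomposition, stratification, agreement and metric checks."""

import numpy as np
import pandas as pd
import pytest

from lncuncert import uncertainty as unc


class TestBinaryEntropy:
    @pytest.mark.parametrize("p,expected", [
        (0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.811278124459133),
    ])
    def test_anchor_values(self, p, expected):
        assert unc.binary_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        p = rng.random(1000)
        np.testing.assert_allclose(unc.binary_entropy(p),
                                   unc.binary_entropy(1 - p))

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            unc.binary_entropy(bad)


class TestOrientScores:
    def test_lncrna_positive_tool_inverted(self):
        p, lab = unc.orient_scores(0.3, positive_class=unc.LNCRNA)
        assert p == pytest.approx(0.7)
        assert lab == unc.CODING

    def test_coding_positive_identity(self):
        p, lab = unc.orient_scores(0.9, positive_class=unc.CODING)
        assert p == pytest.approx(0.9)
        assert lab == unc.CODING

    def test_tie_goes_to_coding(self):
        _, lab = unc.orient_scores(0.5, tool_threshold=0.5)
        assert lab == unc.CODING

    def test_error_names_tool(self):
        with pytest.raises(ValueError, match="cpat2"):
            unc.orient_scores(1.5, tool="cpat2", transcript="tx1")


class TestEnsembleProfile:
    def test_consensus_at_maximal_uncertainty(self):
        prof = unc.ensemble_profile([[0.5] * 8])
        assert prof.loc[0, "H_pred"] == pytest.approx(1.0)
        assert prof.loc[0, "H_exp"] == pytest.approx(1.0)
        assert prof.loc[0, "I_dis"] == pytest.approx(0.0)

    def test_maximal_disagreement(self):
        prof = unc.ensemble_profile([[1.0, 1.0, 1.0, 1.0, 0, 0, 0, 0]])
        row = prof.iloc[0]
        assert (row["H_pred"], row["H_exp"], row["I_dis"]) == \
            pytest.approx((1.0, 0.0, 1.0))

    def test_hand_computed_two_tool_case(self):
        row = unc.ensemble_profile([[0.8, 0.6]]).iloc[0]
        assert row["H_pred"] == pytest.approx(0.88129, abs=1e-4)
        assert row["H_exp"] == pytest.approx(0.84645, abs=1e-4)
        assert row["I_dis"] == pytest.approx(0.03484, abs=1e-4)

    def test_disagreement_nonnegative_property(self, rng):
        # concavity of H: holds for random ensembles of any size 2..8
        for m in range(2, 9):
            P = rng.random((2000, m))
            prof = unc.ensemble_profile(P)
            assert (prof["I_dis"] >= -1e-12).all()

    def test_disagreement_zero_iff_equal(self, rng):
        p = rng.random(500)
        prof = unc.ensemble_profile(np.tile(p[:, None], (1, 5)))
        np.testing.assert_allclose(prof["I_dis"], 0, atol=1e-12)
        P = rng.random((500, 5))
        spread = P.max(axis=1) - P.min(axis=1) > 0.05
        assert (prof2 := unc.ensemble_profile(P)).loc[spread, "I_dis"].min() > 0

    def test_single_tool_rejected(self):
        with pytest.raises(ValueError):
            unc.ensemble_profile([[0.5]])


class TestExcludeIncomplete:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"reference": ["coding"] * 3,
                           "prob_a": [0.1, 0.2, 0.3],
                           "prob_b": [0.9, 0.8, 0.7]})
        kept, report = unc.exclude_incomplete(df)
        assert len(kept) == 3 and report["n_excluded"] == 0

    def test_missing_transcript_excluded_and_reported(self):
        df = pd.DataFrame({"prob_a": [0.1, np.nan], "prob_b": [0.9, 0.8]})
        kept, report = unc.exclude_incomplete(df)
        assert len(kept) == 1
        assert report["missing_per_tool"] == {"a": 1, "b": 0}

    def test_planted_missingness_recovered(self, tiny_cohort):
        kept, report = unc.exclude_incomplete(tiny_cohort.predictions)
        planted = tiny_cohort.ground_truth["predictions"]["missing_ids"]
        assert report["n_excluded"] == len(planted)
        assert not set(planted) & set(kept.index)


class TestStratification:
    def test_percentile_interpolation_rule(self):
        vals = np.arange(1.0, 11.0)
        assert np.quantile(vals, 0.1, method="linear") == pytest.approx(1.9)

    def test_constant_values_collapse(self):
        prof = pd.DataFrame({"H_pred": [0.3] * 20, "I_dis": [0.0] * 20})
        labels = ["coding"] * 10 + ["lncRNA"] * 10
        t = unc.compute_thresholds(prof, labels)
        for cls in unc.CLASSES:
            assert t.per_class[cls]["q10_Hpred"] == \
                t.per_class[cls]["q90_Hpred"] == pytest.approx(0.3)

    def test_low_group_counts_match_printed_class_sizes(self, rng):
        # tie-free values of the two printed class sizes yield the printed
        # low-entropy row: 6,638 coding and 4,528 lncRNA transcripts
        for n_cls, expected in ((66376, 6638), (45276, 4528)):
            h = rng.permutation(n_cls) / n_cls
            prof = pd.DataFrame({"H_pred": h, "I_dis": np.zeros(n_cls)})
            labels = ["coding"] * n_cls
            t = unc.compute_thresholds(prof, labels,
                                        classes=("coding",))
            groups = unc.stratify(prof, labels, t)
            assert (groups == "low").sum() == expected

    def test_boundary_value_is_intermediate(self):
        # a transcript exactly at q10 is NOT low (strict inequality)
        h = np.arange(11) / 10.0
        prof = pd.DataFrame({"H_pred": h, "I_dis": np.zeros(11)})
        labels = ["coding"] * 11
        t = unc.compute_thresholds(prof, labels, classes=("coding",))
        q10 = t.per_class["coding"]["q10_Hpred"]
        at = np.where(np.isclose(h, q10))[0]
        groups = unc.stratify(prof, labels, t)
        assert (groups.iloc[at] == "intermediate").all()

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        n = 5000
        prof = pd.DataFrame({"H_pred": rng.random(n), "I_dis": rng.random(n)})
        labels = np.where(rng.random(n) < 0.6, "coding", "lncRNA")
        t = unc.compute_thresholds(prof, labels)
        groups = unc.stratify(prof, labels, t)
        assert set(groups.unique()) <= {"low", "high", "intermediate"}
        assert len(groups) == n


class TestAgreement:
    def test_categories(self):
        labs = np.array([["coding"] * 8,
                         ["lncRNA"] * 8,
                         ["coding"] * 6 + ["lncRNA"] * 2])
        rec = unc.agreement_category(labs, np.array(["coding"] * 3))
        assert list(rec["category"]) == ["unanimous_correct",
                                         "unanimous_incorrect", "discordant"]
        assert list(rec["near_consensus"]) == [False, False, True]
        assert rec.loc[2, "n_correct"] == 6


class TestEvaluate:
    def test_perfect_predictions(self):
        ref = ["coding"] * 5 + ["lncRNA"] * 5
        rep = unc.evaluate(ref, ref)
        assert rep.balanced_accuracy == rep.macro_f1 == 1.0

    def test_degenerate_all_coding_predictor(self):
        ref = ["coding"] * 90 + ["lncRNA"] * 10
        rep = unc.evaluate(["coding"] * 100, ref)
        assert rep.balanced_accuracy == pytest.approx(0.5)
        assert "lncRNA" in rep.zero_predicted_classes

    def test_balanced_accuracy_is_mean_recall(self):
        # sensitivity 0.9 on coding, specificity 0.7 on lncRNA -> 0.8
        ref = ["coding"] * 10 + ["lncRNA"] * 10
        pred = (["coding"] * 9 + ["lncRNA"] +
                ["lncRNA"] * 7 + ["coding"] * 3)
        assert unc.evaluate(pred, ref).balanced_accuracy == pytest.approx(0.8)

    def test_agrees_with_bruteforce_confusion_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 400))
            ref = np.where(rng.random(n) < 0.5, "coding", "lncRNA")
            if len(np.unique(ref)) < 2:
                continue
            pred = np.where(rng.random(n) < 0.5, "coding", "lncRNA")
            rep = unc.evaluate(pred, ref)
            recalls, precs = [], []
            for cls in ("coding", "lncRNA"):
                tp = np.sum((ref == cls) & (pred == cls))
                recalls.append(tp / np.sum(ref == cls))
                pp = np.sum(pred == cls)
                precs.append(tp / pp if pp else 0.0)
            assert rep.balanced_accuracy == pytest.approx(np.mean(recalls))
            assert rep.macro_precision == pytest.approx(np.mean(precs))
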
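"""Feature-based classifiers: splits, training, evaluation, transfer."""

import numpy as np
import pandas as pd
import pytest

import flimpheno as fp
from flimpheno import classify
from flimpheno.classify import NEGATIVE, POSITIVE


class TestSplit:
    def test_1819_cells_split_1365_454(self):
        df = fp.sample_cell_features(
            {"glycolysis_inhibited": 910, "oxphos_inhibited": 909}, seed=1)
        train, test = classify.split_train_test(df, seed=0)
        assert len(train) == 1365
        assert len(test) == 454

    def test_stratification_preserved(self):
        df = fp.sample_cell_features(
            {"glycolysis_inhibited": 50, "oxphos_inhibited": 50}, seed=2)
        train, test = classify.split_train_test(df, seed=0)
        assert abs((train.group == POSITIVE).sum() - 37.5) <= 1
        assert abs((test.group == POSITIVE).sum() - 12.5) <= 1
        assert set(train.cell_id).isdisjoint(test.cell_id)

    def test_same_seed_same_membership(self, feature_table):
        a, _ = classify.split_train_test(feature_table, seed=3)
        b, _ = classify.split_train_test(feature_table, seed=3)
        assert list(a.cell_id) == list(b.cell_id)

    def test_tiny_class_rejected(self):
        df = fp.sample_cell_features(
            {"glycolysis_inhibited": 1, "oxphos_inhibited": 10}, seed=1)
        with pytest.raises(ValueError):
            classify.split_train_test(df)


class TestTrainEvaluate:
    def test_separable_data_trains_to_high_accuracy(self, feature_table):
        train, test = classify.split_train_test(feature_table, seed=0)
        models = classify.train_models(train, seed=0)
        assert set(models) == {"rft", "svm", "qda"}
        for tag, model in models.items():
            rep = classify.evaluate(model, test, model_tag=tag)
            assert rep.accuracy >= 0.9

    def test_label_shuffle_near_chance(self, feature_table):
        rng = np.random.default_rng(0)
        shuffled = feature_table.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        acc = classify.cross_val_accuracy(
            classify.make_models(seed=0)["rft"], shuffled, seed=0)
        assert abs(acc - 0.5) < 0.1

    def test_confusion_arithmetic(self):
        # hand-built predictions: TP=9, FP=1, FN=1, TN=9
        class Fixed:
            def __init__(self, preds):
                self.preds = np.asarray(preds)

            def predict(self, X):
                return self.preds

            def decision_function(self, X):
                return self.preds.astype(float)

        y = [NEGATIVE] * 10 + [POSITIVE] * 10
        preds = [0] * 9 + [1] + [0] + [1] * 9
        df = pd.DataFrame({"group": y,
                           **{f: np.zeros(20) for f in fp.FEATURE_NAMES}})
        rep = classify.evaluate(Fixed(preds), df)
        assert rep.precision == pytest.approx(0.9)
        assert rep.recall == pytest.approx(0.9)
        assert rep.accuracy == pytest.approx(rep.confusion.trace() / rep.confusion.sum())

    def test_auc_invariant_under_monotone_transform(self, feature_table):
        from sklearn.metrics import roc_auc_score

        y = (feature_table.group == POSITIVE).astype(int)
        s = feature_table["nadh_a1"].to_numpy()
        assert roc_auc_score(y, s) == pytest.approx(
            roc_auc_score(y, np.exp(3 * s)), abs=1e-12)

    def test_cv_folds_partition_data(self, feature_table):
        from sklearn.model_selection import StratifiedKFold

        X = feature_table[fp.FEATURE_NAMES].to_numpy()
        y = (feature_table.group == POSITIVE).to_numpy()
        seen = []
        for _, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            seen.append(te)
        all_idx = np.concatenate(seen)
        assert len(all_idx) == len(feature_table)
        assert len(np.unique(all_idx)) == len(feature_table)


class TestFeatureRanking:
    def test_uninformative_feature_auc_half(self, feature_table):
        df = feature_table.copy()
        df["fad_t1"] = 0.35  # identical across classes
        rank = classify.feature_ranking(df, seed=0)
        assert rank.set_index("feature").loc["fad_t1", "auc"] == pytest.approx(0.5)

    def test_orientation_maximizes_auc(self, feature_table):
        # nadh_a1 rises with the positive class, so its negative must be
        # scored on the descending orientation with the same AUC
        df = feature_table.copy()
        df["fad_t1"] = -df["nadh_a1"]
        rank = classify.feature_ranking(df, seed=0).set_index("feature")
        assert rank.loc["fad_t1", "auc"] == pytest.approx(
            rank.loc["nadh_a1", "auc"], abs=1e-12)
        assert rank.loc["fad_t1", "auc"] >= 0.5
        assert rank.loc["fad_t1", "orientation"] == "descending"
        assert rank.loc["nadh_a1", "orientation"] == "ascending"

    def test_nadh_tm_and_a1_outrank_fad_lifetimes(self, feature_table):
        rank = classify.feature_ranking(feature_table, seed=0).set_index("feature")
        fad_lifetimes = ["fad_tm", "fad_t1", "fad_t2", "fad_a1"]
        for f in ("nadh_tm", "nadh_a1"):
            assert (rank.loc[f, "auc"] > rank.loc[fad_lifetimes, "auc"]).all()


@pytest.fixture(scope="module")
def populations():
    df = fp.sample_cell_features(
        {"control": 200, "glycolysis_inhibited": 200,
         "oxphos_inhibited": 200}, seed=8, batch="A")
    g = df.groupby("group")[fp.FEATURE_NAMES].mean()
    scale = (g.loc["glycolysis_inhibited"] / g.loc["oxphos_inhibited"]).to_dict()
    return df, fp.shifted_population(df, scale, batch="B")


class TestTransfer:
    def test_normalized_transfer_beats_raw(self, populations):
        dfA, dfB = populations
        inhibited = dfA[dfA.group != "control"]
        raw = classify.train_models(inhibited, seed=0)["rft"]
        bb = dfB[dfB.group != "control"]
        yb = (bb.group == POSITIVE).to_numpy()
        raw_acc = (raw.predict(bb[fp.FEATURE_NAMES].to_numpy()) == yb).mean()
        normA = fp.normalize_by_control(dfA, "control")
        norm_model = classify.train_models(normA[normA.group != "control"],
                                           seed=0)["rft"]
        res = fp.transfer_predict(norm_model, dfB, "control")
        mask = (dfB.group != "control").to_numpy()
        norm_acc = (res["predictions"][mask] == bb.group.to_numpy()).mean()
        assert norm_acc >= 0.8
        assert raw_acc < 0.65

    def test_fractions_sum_to_one(self, populations):
        dfA, dfB = populations
        normA = fp.normalize_by_control(dfA, "control")
        model = classify.train_models(normA[normA.group != "control"], seed=0)["rft"]
        res = fp.transfer_predict(model, dfB, "control")
        for g, fr in res["fractions"].items():
            assert fr[POSITIVE] + fr[NEGATIVE] == pytest.approx(1.0)

    def test_missing_control_errors(self, populations):
        dfA, dfB = populations
        model = classify.train_models(dfA[dfA.group != "control"], seed=0)["rft"]
        with pytest.raises(ValueError):
            fp.transfer_predict(model, dfB, "no_such_group")

    def test_all_control_input_no_crash(self, populations):
        dfA, _ = populations
        normA = fp.normalize_by_control(dfA, "control")
        model = classify.train_models(normA[normA.group != "control"], seed=0)["rft"]
        ctrl = dfA[dfA.group == "control"]
        res = fp.transfer_predict(model, ctrl, "control")
        fr = res["fractions"]["control"]
        assert 0.0 <= fr[POSITIVE] <= 1.0
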
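"""Cross-validation, grid search, Butina splits, voting, metrics."""

import numpy as np
import pytest

from _helpers import all_vote_patterns, vote_oracle
from mnqsar.balancing import BalancingConfig
from mnqsar.modeling import (
    EnsembleMember,
    PipelineConfig,
    butina_clusters,
    butina_split,
    cross_validate_ensemble,
    evaluate_predictions,
    grid_search_fit,
    majority_vote,
    stratified_cv,
    train_ensemble,
)


def _planted_X_y(n=100, n_pos=30, noise_cols=5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(y)
    X = rng.normal(size=(n, noise_cols + 1))
    X[:, 0] = y + rng.normal(scale=0.05, size=n)
    return X, y


SMALL_RF = {"n_estimators": 30}


class TestStratifiedCV:
    def test_validation_sets_are_stratified(self):
        X, y = _planted_X_y()
        cfg = PipelineConfig(model="rf", params=SMALL_RF, seed=1)
        report = stratified_cv(cfg, X, y)
        assert len(report.folds) == 10
        for fold in report.folds:
            assert fold["tp"] + fold["tn"] + fold["fp"] + fold["fn"] == 10
            n_pos_val = fold["tp"] + fold["fn"]
            assert 2 <= n_pos_val <= 4  # 3 +/- 1 positives

    def test_fixed_seed_reproduces_folds(self):
        X, y = _planted_X_y()
        cfg = PipelineConfig(model="rf", params=SMALL_RF, seed=2)
        a = stratified_cv(cfg, X, y)
        b = stratified_cv(cfg, X, y)
        assert a.folds == b.folds

    def test_planted_signal_reaches_high_auc(self):
        X, y = _planted_X_y(n=200, n_pos=60)
        cfg = PipelineConfig(model="rf", params=SMALL_RF, seed=3)
        assert stratified_cv(cfg, X, y).means["auc"] >= 0.95

    def test_kfold_mode_partitions_data(self):
        X, y = _planted_X_y()
        cfg = PipelineConfig(model="rf", params=SMALL_RF, seed=4,
                             cv_mode="kfold", outer_folds=5)
        report = stratified_cv(cfg, X, y)
        total_val = sum(f["tp"] + f["tn"] + f["fp"] + f["fn"]
                        for f in report.folds)
        assert total_val == len(y)

    def test_single_class_error(self):
        X, _ = _planted_X_y()
        cfg = PipelineConfig(model="rf", params=SMALL_RF)
        with pytest.raises(ValueError, match="both classes"):
            stratified_cv(cfg, X, np.ones(len(X), dtype=int))

    def test_smote_balancing_runs_inside_folds(self):
        X, y = _planted_X_y(n=120, n_pos=30)
        cfg = PipelineConfig(
            model="rf", params=SMALL_RF, seed=5,
            balancing=BalancingConfig(method="smote", seed=5),
        )
        report = stratified_cv(cfg, X, y)
        assert report.means["auc"] >= 0.9


class TestGridSearch:
    def test_singleton_grid_chosen(self):
        X, y = _planted_X_y()
        cfg = PipelineConfig(model="rf", grid={"n_estimators": [17]}, seed=0,
                             inner_folds=3)
        _, best = grid_search_fit(cfg, X, y)
        assert best == {"n_estimators": 17}

    def test_strong_setting_beats_degenerate_one(self):
        X, y = _planted_X_y(n=150, n_pos=50)
        cfg = PipelineConfig(
            model="rf",
            grid={"n_estimators": [1, 60], "max_depth": [1, None]},
            seed=1, inner_folds=3,
        )
        _, best = grid_search_fit(cfg, X, y)
        assert best["n_estimators"] == 60

    def test_same_seed_same_choice(self):
        X, y = _planted_X_y()
        cfg = PipelineConfig(model="xgb",
                             grid={"n_estimators": [10, 40], "max_depth": [2, 4]},
                             seed=2, inner_folds=3)
        assert grid_search_fit(cfg, X, y)[1] == grid_search_fit(cfg, X, y)[1]

    def test_empty_grid_error(self):
        X, y = _planted_X_y()
        cfg = PipelineConfig(model="rf", grid={}, seed=0)
        cfg.grid = {}
        with pytest.raises(ValueError, match="non-empty"):
            grid_search_fit(cfg, X, y)


class TestButinaSplit:
    # internally identical, mutually disjoint structural families
    FAMILY_A = ["C1CCCCC1"] * 8
    FAMILY_B = ["c1ccc2ccccc2c1OC"] * 2

    def test_duplicates_stay_together(self):
        smiles = ["CCO", "CCO", "CCO", "c1ccccc1", "c1ccccc1",
                  "CC(=O)Nc1ccc(O)cc1", "CCCCCCCC", "NCCN"]
        train, val = butina_split(smiles, val_fraction=0.25, distance_cutoff=0.4)
        for group in ([0, 1, 2], [3, 4]):
            sides = [("train" if i in train else "val") for i in group]
            assert len(set(sides)) == 1

    def test_disjoint_families_land_on_opposite_sides(self):
        smiles = self.FAMILY_A + self.FAMILY_B
        train, val = butina_split(smiles, val_fraction=0.2, distance_cutoff=0.35)
        val_set = set(val)
        in_val = [i for i in range(len(smiles)) if i in val_set]
        # the small aromatic family fills the 20% validation share
        assert in_val == [8, 9]

    def test_split_partitions_everything(self):
        smiles = self.FAMILY_A + self.FAMILY_B
        train, val = butina_split(smiles, val_fraction=0.2, distance_cutoff=0.35)
        assert sorted(train + val) == list(range(len(smiles)))

    def test_zero_cutoff_separates_distinct_structures(self):
        smiles = ["CCO", "CCO", "CCCO", "c1ccccc1"]
        clusters = butina_clusters(smiles, distance_cutoff=0.0)
        assert len(clusters) == 3  # distinct structure count

    def test_everything_in_one_cluster_raises(self):
        with pytest.raises(ValueError, match="one cluster"):
            butina_split(["CCO", "CCO", "CCO"], distance_cutoff=1.01)


class TestMajorityVote:
    def test_examples(self):
        assert majority_vote([np.array([1]), np.array([1]), np.array([0])]).tolist() == [1]
        # tie resolves positive
        assert majority_vote([np.array([1]), np.array([0])]).tolist() == [1]
        assert majority_vote([np.array([0]), np.array([0])]).tolist() == [0]

    @pytest.mark.parametrize("n_members", [2, 3, 4, 5])
    def test_matches_ballot_counting_oracle_exhaustively(self, n_members):
        patterns = all_vote_patterns(n_members)
        # stack every possible single-compound ballot into <=8-compound blocks
        for start in range(0, len(patterns), 8):
            block = np.array(patterns[start:start + 8]).T  # members x compounds
            assert np.array_equal(
                majority_vote(list(block)), vote_oracle(block)
            )

    def test_too_few_members_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            majority_vote([np.array([1, 0])])


class TestEvaluatePredictions:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        out = evaluate_predictions(y, y, scores=y.astype(float))
        assert out["acc"] == out["se"] == out["sp"] == out["auc"] == 1.0

    def test_constructed_confusion(self):
        # TP=3, TN=4, FP=1, FN=2
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        p = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        out = evaluate_predictions(p, y)
        assert out["acc"] == pytest.approx(0.7)
        assert out["se"] == pytest.approx(0.6)
        assert out["sp"] == pytest.approx(0.8)
        assert "auc" not in out  # labels only, AUC omitted

    def test_constant_scores_give_half_auc(self):
        y = np.array([1, 0, 1, 0])
        out = evaluate_predictions(y, y, scores=np.ones(4))
        assert out["auc"] == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.normal(size=50)
        a = evaluate_predictions(y, y, scores=s)["auc"]
        b = evaluate_predictions(y, y, scores=np.exp(3 * s) + 7)["auc"]
        assert a == pytest.approx(b)

    def test_single_class_truth_error(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_predictions(np.array([1, 1]), np.array([1, 1]))


class TestEnsemble:
    def _members(self):
        return [
            EnsembleMember("rf_a", "block_a", "rf", SMALL_RF),
            EnsembleMember("xgb_b", "block_b", "xgb", {"n_estimators": 30}),
        ]

    def test_train_and_predict(self):
        X, y = _planted_X_y(n=120, n_pos=40)
        features = {"block_a": X, "block_b": X[:, :3]}
        ensemble = train_ensemble(self._members(), features, y, seed=0)
        pred = ensemble.predict(features)
        assert set(np.unique(pred)) <= {0, 1}
        assert (pred == y).mean() > 0.9

    def test_needs_two_members(self):
        X, y = _planted_X_y()
        with pytest.raises(ValueError, match="at least 2"):
            train_ensemble([self._members()[0]], {"block_a": X}, y)

    def test_members_must_share_compounds(self):
        X, y = _planted_X_y()
        features = {"block_a": X, "block_b": X[:-1]}
        with pytest.raises(ValueError, match="identical compounds"):
            train_ensemble(self._members(), features, y)

    def test_cv_report_has_no_auc(self):
        X, y = _planted_X_y(n=120, n_pos=40)
        features = {"block_a": X, "block_b": X[:, :3]}
        report = cross_validate_ensemble(self._members(), features, y,
                                         outer_folds=3, seed=1)
        assert "auc" not in report.means
        assert report.means["acc"] > 0.8
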
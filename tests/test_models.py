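"""OOB scoring, per-target forests, hyperparameter calibration."""

import numpy as np
import pytest

from finnet.dataset import CATEGORICAL, ValidationError, preprocess, shuffle_columns
from finnet.models import (
    DEFAULT_HP,
    HPCalibrationResult,
    HPSet,
    oob_f1,
    oob_r2,
    performance_group,
    random_search_hp,
    run_all_targets,
    select_frequent_hp,
    target_seed,
    train_target_model,
)
from finnet.ontology import TargetSpec, build_target_spec
from finnet.synth import SynthConfig, generate_synthetic_dataset

from conftest import make_matrix


def votes(pairs):
    """[(neg_votes, pos_votes), ...] -> vote tally array."""
    return np.array(pairs, dtype=np.int64)


class TestOobF1:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 1, 0])
        v = votes([(3, 0), (0, 3), (1, 2), (2, 1)])
        assert oob_f1(v, labels) == 1.0

    def test_all_negative_with_positives_present(self):
        labels = np.array([1, 1, 0])
        v = votes([(3, 0), (2, 0), (4, 0)])
        assert oob_f1(v, labels) == 0.0

    def test_tp1_fp1_fn3(self):
        # predictions: pos, pos, neg, neg, neg ; labels: pos, neg, pos, pos, pos
        labels = np.array([1, 0, 1, 1, 1])
        v = votes([(0, 2), (0, 2), (2, 0), (2, 0), (2, 0)])
        assert oob_f1(v, labels) == pytest.approx(1 / 3)

    def test_tie_votes_predict_positive(self):
        labels = np.array([1])
        assert oob_f1(votes([(2, 2)]), labels) == 1.0

    def test_unvoted_genes_excluded(self):
        labels = np.array([1, 0])
        # second gene never OOB: excluded, so score is perfect
        assert oob_f1(votes([(0, 1), (0, 0)]), labels) == 1.0

    def test_no_votes_anywhere_is_error(self):
        with pytest.raises(ValidationError, match="n_estimators"):
            oob_f1(votes([(0, 0), (0, 0)]), np.array([0, 1]))


class TestOobR2:
    def test_exact_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        assert oob_r2(y.copy(), y) == 1.0

    def test_mean_predictions_score_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert oob_r2(np.full(3, 2.0), y) == 0.0

    def test_anti_predictions_negative(self):
        y = np.array([-1.0, 1.0])
        assert oob_r2(-y, y) == -3.0  # SS_res 8, SS_tot 2

    def test_nan_predictions_excluded(self):
        y = np.array([1.0, 2.0, 3.0, 100.0])
        preds = np.array([1.0, 2.0, 3.0, np.nan])
        assert oob_r2(preds, y) == 1.0

    def test_constant_target_is_error(self):
        with pytest.raises(ValidationError, match="constant"):
            oob_r2(np.array([1.0, 2.0]), np.array([5.0, 5.0]))


class TestHPSet:
    def test_fraction_maps_to_ceiling(self):
        assert HPSet(max_features=0.2).resolve_max_features(58) == 12  # ceil(11.6)
        assert HPSet(max_features="sqrt").resolve_max_features(100) == 10

    @pytest.mark.parametrize("bad", [
        dict(ccp_alpha=-0.1), dict(max_features=0.0), dict(max_features=1.5),
        dict(n_estimators=0), dict(max_depth=0),
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValidationError):
            HPSet(**bad)


def _planted_matrix(seed, kind="categorical", n=300):
    """Matrix whose target column is an exact copy of one predictor."""
    rng = np.random.default_rng(seed)
    if kind == "categorical":
        src = (rng.random(n) < 0.4).astype(float)
    else:
        src = rng.standard_normal(n)
    cols = {"target": src.copy(), "twin": src.copy()}
    for j in range(8):
        cols[f"bg{j}"] = rng.standard_normal(n)
    return preprocess(make_matrix(cols))


class TestTrainTargetModel:
    @pytest.mark.parametrize("kind, floor", [("categorical", 0.9), ("continuous", 0.9)])
    def test_planted_copy_recovered(self, kind, floor):
        """An exact-copy predictor dominates importance and the OOB score."""
        # half the predictors per split, so each tree sees the twin early
        hp = HPSet(ccp_alpha=0.001, max_features=0.5, n_estimators=50, max_depth=200)
        for seed in range(3):
            m = _planted_matrix(seed, kind)
            res = train_target_model(m, build_target_spec(m, "target"), hp, seed)
            assert res.score > floor
            assert max(res.importances, key=res.importances.get) == "twin"
            assert 0 <= sum(res.importances.values()) <= 1 + 1e-6

    def test_shuffled_matrix_destroys_score(self):
        m = _planted_matrix(0, "categorical")
        shuffled = shuffle_columns(m, seed=9)
        res = train_target_model(
            shuffled, build_target_spec(shuffled, "target"), DEFAULT_HP, 0
        )
        # balanced-ish classes, no signal: should not beat chance meaningfully
        assert res.score < 0.5

    def test_single_class_target_is_error(self):
        m = make_matrix({"t": [1.0] * 10, "x": list(range(10))},
                        kinds={"t": CATEGORICAL}, preprocessed=True)
        with pytest.raises(ValidationError, match="degenerate"):
            train_target_model(m, TargetSpec("t", ("x",)), DEFAULT_HP, 0)

    def test_empty_predictors_is_error(self):
        m = _planted_matrix(0)
        with pytest.raises(ValidationError, match="empty predictor"):
            train_target_model(m, TargetSpec("target", ()), DEFAULT_HP, 0)

    def test_unpreprocessed_matrix_rejected(self):
        m = make_matrix({"t": [0.0, 1.0], "x": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="preprocessed"):
            train_target_model(m, TargetSpec("t", ("x",)), DEFAULT_HP, 0)


class TestRunAllTargets:
    def test_all_eligible_covered_and_deterministic(self):
        cfg = SynthConfig(n_genes=150, n_blocks=2, continuous_per_block=2,
                          categorical_per_block=2, n_noise_features=2,
                          n_term_parents=1, genes_per_child=25, missing_rate=0.0, seed=4)
        matrix, truth = generate_synthetic_dataset(cfg)
        mp = preprocess(matrix)
        r1, f1 = run_all_targets(mp, truth.to_dag(), DEFAULT_HP, base_seed=2)
        r2, f2 = run_all_targets(mp, truth.to_dag(), DEFAULT_HP, base_seed=2)
        assert [r.target for r in r1] == [r.target for r in r2]
        assert [r.score for r in r1] == [r.score for r in r2]
        assert [r.importances for r in r1] == [r.importances for r in r2]
        assert f1 == f2 == {}

    def test_parallelism_does_not_change_results(self):
        cfg = SynthConfig(n_genes=120, n_blocks=2, continuous_per_block=2,
                          categorical_per_block=1, n_noise_features=1,
                          n_term_parents=0, missing_rate=0.0, seed=6)
        matrix, _ = generate_synthetic_dataset(cfg)
        mp = preprocess(matrix)
        serial, _ = run_all_targets(mp, None, DEFAULT_HP, base_seed=3, n_jobs=1)
        parallel, _ = run_all_targets(mp, None, DEFAULT_HP, base_seed=3, n_jobs=2)
        assert [(r.target, r.score, r.seed) for r in serial] == \
               [(r.target, r.score, r.seed) for r in parallel]
        assert [r.importances for r in serial] == [r.importances for r in parallel]

    def test_failures_collected_not_dropped(self):
        m = make_matrix({"const": [1.0] * 30, "x": [float(i % 2) for i in range(30)],
                         "y": list(np.linspace(0, 1, 30))},
                        kinds={"const": CATEGORICAL}, preprocessed=True)
        results, failures = run_all_targets(m, None, DEFAULT_HP, base_seed=0)
        assert {r.target for r in results} == {"x", "y"}
        assert "const" in failures and "degenerate" in failures["const"]


def test_target_seed_stable_and_bounded():
    s = target_seed(42, "GO:0005829")
    assert s == target_seed(42, "GO:0005829")
    assert s != target_seed(43, "GO:0005829")
    assert s != target_seed(42, "GO:0016020")
    assert 0 <= s < 2**31


@pytest.mark.parametrize("score, group", [
    (0.71, "high"), (0.7, "high"), (0.5, "medium"), (0.69, "medium"), (0.49, "low"),
])
def test_performance_group_thresholds(score, group):
    assert performance_group(score) == group


class TestSelectFrequentHP:
    @staticmethod
    def _result(hp, score=0.8):
        return HPCalibrationResult(target=f"t{id(hp)}", best_hp=hp,
                                   best_score=score, group=performance_group(score))

    def test_individual_takes_per_field_modes(self):
        hps = [HPSet(ccp_alpha=0.0, n_estimators=50),
               HPSet(ccp_alpha=0.0, n_estimators=100),
               HPSet(ccp_alpha=0.1, n_estimators=100)]
        chosen = select_frequent_hp([self._result(h) for h in hps], method="individual")
        assert chosen.ccp_alpha == 0.0
        assert chosen.n_estimators == 100

    def test_group_tie_broken_by_grid_order(self):
        grid = {"ccp_alpha": [0.1, 0.0], "max_features": [0.2],
                "n_estimators": [50], "max_depth": [200]}
        hps = [HPSet(ccp_alpha=0.0), HPSet(ccp_alpha=0.1)]
        chosen = select_frequent_hp([self._result(h) for h in hps],
                                    method="group", grid=grid)
        assert chosen.ccp_alpha == 0.1  # declared first in the grid

    def test_single_result_identity_under_both_methods(self):
        hp = HPSet(ccp_alpha=0.001, n_estimators=200)
        results = [self._result(hp)]
        assert select_frequent_hp(results, "individual") == hp
        assert select_frequent_hp(results, "group") == hp

    def test_low_only_results_fall_back_to_all(self, caplog):
        results = [self._result(HPSet(), score=0.2)]
        with caplog.at_level("WARNING"):
            assert select_frequent_hp(results) == HPSet()
        assert "falling back" in caplog.text

    def test_empty_results_is_error(self):
        with pytest.raises(ValidationError):
            select_frequent_hp([])


class TestRandomSearch:
    def test_single_combination_grid_is_forced_choice(self):
        m = _planted_matrix(1)
        grid = {"ccp_alpha": [0.001], "max_features": [0.5],
                "n_estimators": [20], "max_depth": [10]}
        out = random_search_hp(m, ["target"], grid=grid, n_iter=3, seed=0)
        assert len(out) == 1
        assert out[0].best_hp == HPSet(0.001, 0.5, 20, 10)
        assert out[0].group == performance_group(out[0].best_score)

    def test_superior_configuration_wins(self):
        """1 tree vs 200 trees on noisy planted data: big forest should win."""
        grid = {"ccp_alpha": [0.0], "max_features": [0.5],
                "n_estimators": [1, 200], "max_depth": [None]}
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            z = rng.standard_normal(n)
            y = (z + 0.3 * rng.standard_normal(n) > 0.3).astype(float)
            cols = {"t": y}
            for j in range(6):
                cols[f"p{j}"] = z + 0.6 * rng.standard_normal(n)
            m = preprocess(make_matrix(cols))
            res = random_search_hp(m, ["t"], grid=grid, n_iter=2, seed=seed)
            chosen = select_frequent_hp(res, "individual", grid)
            wins += chosen.n_estimators == 200
        assert wins >= 9
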
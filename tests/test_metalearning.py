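import numpy as np
import pandas as pd
import pytest

from metaclust import (
    enumerate_algorithm_space,
    generate_meta_benchmark,
    planted_component_effect,
    preprocess_meta_table,
    rank_algorithms,
    train_and_select,
)
from metaclust.metalearning import (
    MetaModel,
    MetaTable,
    ModelFormatError,
    SchemaMismatchError,
    evaluate_metamodel,
    load_model,
    save_model,
)
from metaclust.synthetic import SyntheticConfig, generate_expression

SPECS = enumerate_algorithm_space()[::28][:18]


@pytest.fixture(scope="module")
def oracle_benchmark():
    effect = planted_component_effect(base=0.2, level="CORREL", boost=0.3, noise_sd=0.02)
    return generate_meta_benchmark(30, SPECS, seed=101, effect=effect)


@pytest.fixture(scope="module")
def trained(oracle_benchmark):
    _, table = oracle_benchmark
    best, _ = train_and_select(table, regressors=("SVM",), seed=2)
    return best, table


@pytest.fixture(scope="module")
def planted_model(oracle_benchmark):
    _, table = oracle_benchmark
    best, _ = train_and_select(table, regressors=("LR",), seed=4)
    return best


@pytest.fixture(scope="module")
def new_dataset():
    return generate_expression(SyntheticConfig(seed=404, separation=6.0))


class TestPreprocess:
    def test_nominal_columns_expand_to_full_vocabularies(self, oracle_benchmark):
        _, table = oracle_benchmark
        x, y, recipe = preprocess_meta_table(table)
        init_cols = [n for n in recipe.feature_names if n.startswith("init=")]
        dist_cols = [n for n in recipe.feature_names if n.startswith("distance=")]
        assert len(init_cols) == 7 and len(dist_cols) == 4
        assert x.shape == (len(table), len(recipe.feature_names))
        assert len(y) == len(table)

    def test_missing_numeric_values_imputed_with_column_mean(self, oracle_benchmark):
        _, table = oracle_benchmark
        frame = table.frame.copy()
        frame.loc[frame.index[0], "xb"] = np.nan
        x, _, recipe = preprocess_meta_table(MetaTable(frame))
        col = recipe.feature_names.index("xb")
        others = pd.to_numeric(frame["xb"], errors="coerce").dropna()
        assert x[0, col] == pytest.approx(others.mean())

    def test_empty_table_rejected(self, oracle_benchmark):
        _, table = oracle_benchmark
        with pytest.raises(ValueError, match="empty"):
            preprocess_meta_table(MetaTable(table.frame.iloc[:0]))


class TestTrainAndSelect:
    def test_noiseless_linear_labels_make_lr_exact_and_selected(self, oracle_benchmark):
        _, table = oracle_benchmark
        frame = table.frame.copy()
        frame["AMI"] = 0.1 + 0.05 * frame["mean_skewness"] + 0.02 * frame["compact"]
        best, reports = train_and_select(MetaTable(frame), regressors=("LR", "RBFN"), seed=3)
        assert best.regressor_kind == "LR"
        assert reports["LR"]["MAE"] < 1e-8

    def test_constant_labels_fall_to_documented_tie_order(self, oracle_benchmark):
        _, table = oracle_benchmark
        frame = table.frame.copy()
        frame["AMI"] = 0.42
        best, reports = train_and_select(MetaTable(frame), regressors=("LR", "LMSR"), seed=3)
        assert best.regressor_kind == "LR"
        assert reports["LR"]["MAE"] == pytest.approx(0.0, abs=1e-10)

    def test_nonlinear_labels_beat_linear_regression(self, oracle_benchmark):
        _, table = oracle_benchmark
        rng = np.random.default_rng(7)
        frame = table.frame.copy()
        # a continuously varying dataset descriptor, rescaled to ~[0, 2pi]
        z = frame["log2_n_instances"].to_numpy(dtype=float)
        z = (z - z.min()) / (z.max() - z.min()) * 2 * np.pi
        frame["AMI"] = np.sin(z) * 0.4 + 0.5 + rng.normal(0, 0.05, size=len(frame))
        best, reports = train_and_select(
            MetaTable(frame), regressors=("LR", "SVM", "RBFN"), seed=5
        )
        assert best.regressor_kind in ("SVM", "RBFN")
        assert reports[best.regressor_kind]["RMSE"] < reports["LR"]["RMSE"]

    def test_row_order_does_not_change_selection_or_metrics(self, oracle_benchmark):
        _, table = oracle_benchmark
        best_a, rep_a = train_and_select(table, regressors=("LR", "RBFN"), seed=9)
        shuffled = table.frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        best_b, rep_b = train_and_select(MetaTable(shuffled), regressors=("LR", "RBFN"), seed=9)
        assert best_a.regressor_kind == best_b.regressor_kind
        for kind in rep_a:
            assert rep_a[kind]["RMSE"] == pytest.approx(rep_b[kind]["RMSE"], abs=1e-9)

    def test_too_small_table_rejected(self, oracle_benchmark):
        _, table = oracle_benchmark
        with pytest.raises(ValueError, match="at least 50"):
            train_and_select(MetaTable(table.frame.iloc[:30]))

    def test_grouped_split_keeps_datasets_on_one_side(self, oracle_benchmark):
        from metaclust.metalearning import _split_keys

        _, table = oracle_benchmark
        train_mask, test_mask = _split_keys(table.frame, 0.3, seed=2, group_by_dataset=True)
        train_ids = set(table.frame.loc[train_mask, "dataset_id"])
        test_ids = set(table.frame.loc[test_mask, "dataset_id"])
        assert not train_ids & test_ids


class TestEvaluate:
    def test_perfect_predictions_give_zeros(self, oracle_benchmark):
        _, table = oracle_benchmark
        best, _ = train_and_select(table, regressors=("LR",), seed=1)

        class Echo:
            def __init__(self, y):
                self.y = y

            def predict(self, x):
                return self.y

        echo = MetaModel("LR", Echo(table.frame["AMI"].to_numpy(float)), best.recipe, {})
        mae, rmse, sd = evaluate_metamodel(echo, table)
        assert (mae, rmse, sd) == (0.0, 0.0, 0.0)

    def test_constant_prediction_errors_match_direct_arithmetic(self, oracle_benchmark):
        _, table = oracle_benchmark
        y = table.frame["AMI"].to_numpy(float)
        c = 0.4

        class Const:
            def predict(self, x):
                return np.full(len(x), c)

        best, _ = train_and_select(table, regressors=("LR",), seed=1)
        model = MetaModel("LR", Const(), best.recipe, {})
        mae, rmse, sd = evaluate_metamodel(model, table)
        err = np.abs(y - c)
        assert mae == pytest.approx(err.mean())
        assert rmse == pytest.approx(np.sqrt((err**2).mean()))
        assert sd == pytest.approx(err.std(ddof=1))
        assert rmse >= mae


class TestPersistence:
    def test_round_trip_predicts_bitwise_identically(self, trained, tmp_path):
        model, table = trained
        path = tmp_path / "m.joblib"
        save_model(model, path)
        loaded = load_model(path)
        rows = table.frame.iloc[:100]
        np.testing.assert_array_equal(model.predict(rows), loaded.predict(rows))

    def test_truncated_file_is_a_load_error(self, trained, tmp_path):
        model, _ = trained
        path = tmp_path / "m.joblib"
        save_model(model, path)
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_foreign_file_is_a_format_error(self, tmp_path):
        import joblib

        path = tmp_path / "other.joblib"
        joblib.dump([1, 2, 3], path)
        with pytest.raises(ModelFormatError, match="not a metaclust model"):
            load_model(path)

    def test_schema_mismatch_detected_at_predict(self, trained):
        model, table = trained
        broken = table.frame.drop(columns=["xb"])
        with pytest.raises(SchemaMismatchError, match="xb"):
            model.predict(broken)


class TestRanking:
    def test_ranking_covers_candidates_sorted_non_increasing(self, planted_model, new_dataset):
        ranking = rank_algorithms(planted_model, new_dataset, SPECS, mode="a_priori")
        assert len(ranking) == len(SPECS)
        assert set(ranking["algorithm_name"]) == {s.full_name for s in SPECS}
        assert (np.diff(ranking["predicted_ami"].to_numpy()) <= 1e-12).all()

    def test_planted_component_occupies_the_top_block(self, planted_model, new_dataset):
        ranking = rank_algorithms(planted_model, new_dataset, SPECS, mode="a_priori")
        n_correl = sum(1 for s in SPECS if s.distance == "CORREL")
        top = ranking.head(n_correl)["algorithm_name"]
        assert all("CORREL" in name for name in top)

    def test_single_candidate_either_mode(self, planted_model, new_dataset):
        for mode in ("a_priori", "post_hoc"):
            ranking = rank_algorithms(planted_model, new_dataset, SPECS[:1], mode=mode, k=3)
            assert len(ranking) == 1

    def test_post_hoc_fills_internal_measures_and_still_ranks(self, planted_model, new_dataset):
        ranking = rank_algorithms(planted_model, new_dataset, SPECS[:4], mode="post_hoc", k=3, seed=1)
        assert len(ranking) == 4
        assert ranking["predicted_ami"].notna().all()

    def test_determinism_of_training_and_ranking(self, oracle_benchmark, new_dataset):
        _, table = oracle_benchmark
        a, _ = train_and_select(table, regressors=("LR", "SVM"), seed=6)
        b, _ = train_and_select(table, regressors=("LR", "SVM"), seed=6)
        assert a.regressor_kind == b.regressor_kind
        ra = rank_algorithms(a, new_dataset, SPECS, mode="a_priori")
        rb = rank_algorithms(b, new_dataset, SPECS, mode="a_priori")
        pd.testing.assert_frame_equal(ra, rb)
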
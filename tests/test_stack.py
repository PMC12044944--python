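"""Base matrix, probability-feature assembly, selection, meta-classifier."""

import numpy as np
import pytest

from chemstack import (
    StackConfig,
    build_pfv,
    fit_meta,
    fit_stack,
    oof_probability,
    predict,
    rank_pfs_mdgi,
    screen_library,
    select_feature_subset,
    train_base_matrix,
    tune_base_classifier,
)
from chemstack.errors import (
    ConfigurationError,
    IncompleteMatrixError,
    InputError,
    InvariantViolationError,
)
from chemstack.sampling import make_balanced_subsets
from chemstack.stack import (
    ALGORITHM_ORDER,
    FAMILY_ORDER,
    BaseModelKey,
    PFVMatrix,
    enumerate_keys,
    make_estimator,
)
from chemstack.synthetic import generate_block_dataset, generate_feature_dataset


def separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.normal(size=(n, 5)) + 4.0 * y[:, None]
    return X, y


def small_stack(seed=0, algorithms=("KNN", "PLS"), n_pos=60, n_neg=20, k=3):
    blocks, y = generate_block_dataset(
        n_pos, n_neg, {"B1": (25, 5), "B2": (20, 4)}, 0.5, seed=seed
    )
    config = StackConfig(
        algorithms=algorithms, families=("B1", "B2"), k=k,
        base_folds=3, selection_folds=3, seed=seed,
    )
    return blocks, y, config


class TestKeyEnumeration:
    def test_default_roster_yields_150_keys(self):
        keys = enumerate_keys(ALGORITHM_ORDER, FAMILY_ORDER, 5)
        assert len(keys) == 150
        assert len(set(keys)) == 150

    def test_column_order_algorithm_major(self):
        keys = enumerate_keys(("KNN", "RF"), ("B1", "B2"), 3)
        assert len(keys) == 12
        assert keys[0] == BaseModelKey("KNN", "B1", 1)
        assert keys[1] == BaseModelKey("KNN", "B1", 2)
        assert keys[3] == BaseModelKey("KNN", "B2", 1)
        assert keys[6] == BaseModelKey("RF", "B1", 1)

    @pytest.mark.parametrize("a,d,k", [(1, 1, 1), (2, 2, 3), (2, 1, 4)])
    def test_width_is_cartesian_product(self, a, d, k):
        algs = ("KNN", "PLS", "RF", "SVM")[:a]
        fams = tuple(f"B{i}" for i in range(d))
        assert len(enumerate_keys(algs, fams, k)) == a * d * k


class TestAlgorithmRoster:
    @pytest.mark.parametrize("algorithm", ALGORITHM_ORDER)
    def test_every_algorithm_fits_and_emits_probabilities(self, algorithm):
        X, y = separable_data(n=30, seed=1)
        est = make_estimator(algorithm, seed=0).fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (30, 2)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            make_estimator("DNN")


class TestTuning:
    def test_separable_data_reaches_perfect_cv_mcc(self):
        X, y = separable_data()
        model = tune_base_classifier("RF", X, y, folds=5, seed=0)
        assert model.cv_mcc_ == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        X, y = separable_data()
        with pytest.raises(ConfigurationError):
            tune_base_classifier("KNN", X, y, grid={})

    def test_knn_invariant_to_duplicated_features(self):
        # doubling every column scales all pairwise distances uniformly
        X, y = separable_data(seed=3)
        Xdup = np.hstack([X, X])
        m1 = make_estimator("KNN").fit(X, y)
        m2 = make_estimator("KNN").fit(Xdup, y)
        assert np.array_equal(
            m1.predict_proba(X), m2.predict_proba(Xdup)
        )


class TestOofProbability:
    def test_reproducible_under_seed(self):
        X, y = separable_data()
        est = make_estimator("RF", seed=1)
        a = oof_probability(est, X, y, folds=5, seed=2)
        b = oof_probability(est, X, y, folds=5, seed=2)
        assert np.array_equal(a, b)

    def test_informative_data_ranks_positives_higher(self):
        X, y = separable_data(seed=5)
        p = oof_probability(make_estimator("KNN"), X, y, folds=5, seed=0)
        assert p[y == 1].mean() > p[y == 0].mean()

    def test_more_folds_than_samples_rejected(self):
        X, y = separable_data(n=9 * 2)[0][:9], np.array([1, 1, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(InputError):
            oof_probability(make_estimator("KNN"), X, y, folds=10)


class TestPfvAssembly:
    def test_width_and_range(self):
        blocks, y, config = small_stack()
        subsets = make_balanced_subsets(
            np.flatnonzero(y == 1), np.flatnonzero(y == 0), k=3, seed=0
        )
        base = train_base_matrix(blocks, y, subsets, config)
        pfv = build_pfv(blocks, base, mode="train")
        assert pfv.width == 2 * 2 * 3  # A * D * K
        assert pfv.matrix.shape == (len(y), 12)
        assert pfv.matrix.min() >= 0 and pfv.matrix.max() <= 1
        assert not np.isnan(pfv.matrix).any()
        assert pfv.columns == enumerate_keys(("KNN", "PLS"), ("B1", "B2"), 3)

    def test_apply_mode_scores_everything_with_fitted_models(self):
        blocks, y, config = small_stack(seed=2)
        subsets = make_balanced_subsets(
            np.flatnonzero(y == 1), np.flatnonzero(y == 0), k=3, seed=0
        )
        base = train_base_matrix(blocks, y, subsets, config)
        train_pfv = build_pfv(blocks, base, mode="train")
        apply_pfv = build_pfv(blocks, base, mode="apply")
        assert apply_pfv.matrix.shape == train_pfv.matrix.shape
        # outside a model's own subset the two modes agree
        key = apply_pfv.columns[0]
        outside = np.setdiff1d(
            np.arange(len(y)), np.asarray(base.subsets[0].ids)
        )
        assert np.allclose(
            train_pfv.matrix[outside, 0], apply_pfv.matrix[outside, 0]
        )

    def test_missing_base_model_is_named(self):
        blocks, y, config = small_stack()
        subsets = make_balanced_subsets(
            np.flatnonzero(y == 1), np.flatnonzero(y == 0), k=3, seed=0
        )
        base = train_base_matrix(blocks, y, subsets, config)
        del base.models[BaseModelKey("PLS", "B2", 3)]
        with pytest.raises(IncompleteMatrixError, match="PLS-B2-BTS3"):
            build_pfv(blocks, base, mode="train")

    def test_nan_entries_rejected(self):
        with pytest.raises(InvariantViolationError):
            PFVMatrix(
                matrix=np.array([[0.5, np.nan]]),
                columns=[BaseModelKey("KNN", "B1", 1),
                         BaseModelKey("KNN", "B1", 2)],
            )


class TestMdgiRanking:
    def test_planted_column_ranks_first_across_seeds(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 60 + [0] * 60)
        hits = 0
        for seed in range(10):
            X = rng.random((120, 20))
            X[:, 7] = y * 0.9 + rng.random(120) * 0.1  # strong signal
            pfv = PFVMatrix(X, enumerate_keys(("KNN",), ("B",), 20))
            ranking, _ = rank_pfs_mdgi(pfv, y, seed=seed, n_seeds=3,
                                       n_trees=200)
            hits += ranking[0] == 7
        assert hits >= 9

    def test_duplicated_column_splits_importance(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 60 + [0] * 60)
        X = rng.random((120, 10))
        X[:, 0] = y * 0.8 + rng.random(120) * 0.2
        pfv_single = PFVMatrix(X, enumerate_keys(("KNN",), ("B",), 10))
        _, imp_single = rank_pfs_mdgi(pfv_single, y, seed=0, n_seeds=3)
        Xdup = np.hstack([X, X[:, [0]]])
        pfv_dup = PFVMatrix(Xdup, enumerate_keys(("KNN",), ("B",), 11))
        ranking, imp_dup = rank_pfs_mdgi(pfv_dup, y, seed=0, n_seeds=3)
        assert {0, 10} <= set(ranking[:3])
        combined = imp_dup[0] + imp_dup[10]
        assert combined == pytest.approx(imp_single[0], rel=0.4)

    def test_all_constant_matrix_rejected(self):
        X = np.full((20, 4), 0.5)
        pfv = PFVMatrix(X, enumerate_keys(("KNN",), ("B",), 4))
        with pytest.raises(InputError):
            rank_pfs_mdgi(pfv, np.array([1] * 10 + [0] * 10))


class TestSelection:
    @staticmethod
    def _signal_pfv(seed=0, width=20, n=80):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.random((n, width)) * 0.1
        X[:, 0] = y * 0.9 + rng.random(n) * 0.1
        return PFVMatrix(X, enumerate_keys(("KNN",), ("B",), width)), y

    def test_single_candidate_grid(self):
        pfv, y = self._signal_pfv()
        sel = select_feature_subset(np.arange(20), pfv, y, grid=[10], folds=4)
        assert sel.chosen_m == 10
        assert sel.grid == [10]

    def test_tie_broken_toward_smaller_m(self):
        # columns beyond the signal are pure zeros: every m gives the
        # same CV predictions, so the tie rule must pick the smallest
        pfv, y = self._signal_pfv()
        pfv.matrix[:, 1:] = 0.0
        sel = select_feature_subset(np.arange(20), pfv, y,
                                    grid=[5, 10, 15], folds=4)
        assert sel.chosen_m == 5

    def test_grid_beyond_width_truncated_with_warning(self):
        pfv, y = self._signal_pfv()
        with pytest.warns(UserWarning, match="truncated"):
            sel = select_feature_subset(
                np.arange(20), pfv, y, grid=[10, 20, 30], folds=4
            )
        assert sel.grid == [10, 20]

    def test_empty_grid_rejected(self):
        pfv, y = self._signal_pfv()
        with pytest.raises(ConfigurationError):
            select_feature_subset(np.arange(20), pfv, y, grid=[], folds=4)

    def test_selected_columns_beat_worst_columns(self):
        from sklearn.model_selection import cross_val_predict

        from chemstack.metrics import compute_metrics, confusion
        from chemstack.stack import _meta_estimator, _stratified_folds

        pfv, y = self._signal_pfv(seed=6, width=30, n=100)
        ranking, scores = rank_pfs_mdgi(pfv, y, seed=0, n_seeds=3)
        sel = select_feature_subset(ranking, pfv, y, grid=[5], folds=5,
                                    scores=scores)
        worst = ranking[::-1][:5]
        cv = _stratified_folds(y, 5, 0)
        preds = cross_val_predict(
            _meta_estimator(0), pfv.matrix[:, worst], y, cv=cv
        )
        worst_mcc = compute_metrics(confusion(y, preds)).mcc
        assert sel.cv_mcc_per_m[5] >= worst_mcc


class TestMetaAndEndToEnd:
    def test_separable_pfv_reaches_perfect_training_bacc(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 30 + [0] * 30)
        X = np.column_stack([y * 0.8 + 0.1, rng.random(60)])
        pfv = PFVMatrix(X, enumerate_keys(("KNN",), ("B",), 2))
        sel = select_feature_subset(np.array([0, 1]), pfv, y, grid=[1],
                                    folds=3)
        model = fit_meta(pfv, y, sel)
        proba = model.meta.predict_proba(pfv.select(sel.chosen_columns))[:, 1]
        from chemstack.metrics import evaluate

        assert evaluate(y, proba).bacc == 1.0

    def test_refit_same_seed_identical_predictions(self):
        blocks, y, config = small_stack(seed=9)
        m1, _ = fit_stack(blocks, y, config)
        m2, _ = fit_stack(blocks, y, config)
        assert np.array_equal(
            m1.predict_from_blocks(blocks), m2.predict_from_blocks(blocks)
        )

    def test_smiles_predictions_in_unit_interval(self, smiles_model):
        from chemstack import SyntheticSpec, generate_smiles_dataset

        model, _, _ = smiles_model
        fresh = generate_smiles_dataset(
            SyntheticSpec(n_active=40, n_inactive=10, seed=99)
        )
        table = predict(model, fresh.smiles)
        assert table["probability"].between(0, 1).all()
        assert table["error"].isna().all()

    def test_training_actives_score_above_half_on_average(self, smiles_model):
        model, _, ds = smiles_model
        table = predict(model, ds.smiles)
        proba = table["probability"].to_numpy()
        assert proba[ds.labels == 1].mean() > 0.5
        assert proba[ds.labels == 1].mean() > proba[ds.labels == 0].mean()

    def test_repeated_compound_scores_identically(self, smiles_model):
        model, _, ds = smiles_model
        smi = ds.smiles[0]
        table = predict(model, [smi, "CCO", smi])
        assert table.loc[0, "probability"] == table.loc[2, "probability"]

    def test_unparsable_entry_does_not_abort_batch(self, smiles_model):
        model, _, ds = smiles_model
        table = predict(model, [ds.smiles[0], ")("])
        assert np.isnan(table.loc[1, "probability"])
        assert table.loc[1, "error"]
        assert np.isfinite(table.loc[0, "probability"])


class TestArtifactBundle:
    def test_save_load_roundtrip_preserves_predictions(
        self, smiles_model, tmp_path
    ):
        from chemstack import MetaModel

        model, _, ds = smiles_model
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = MetaModel.load(path)
        a = predict(model, ds.smiles[:5])["probability"]
        b = predict(loaded, ds.smiles[:5])["probability"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_load_refuses_mismatched_feature_registry(
        self, smiles_model, tmp_path, monkeypatch
    ):
        from chemstack import MetaModel
        from chemstack import featurize

        model, _, _ = smiles_model
        path = tmp_path / "model.joblib"
        model.save(path)
        patched = dict(featurize.FAMILY_REGISTRY)
        patched["MACCS"] = (167, "binary", patched["MACCS"][2])
        monkeypatch.setattr(featurize, "FAMILY_REGISTRY", patched)
        with pytest.raises(ConfigurationError, match="registry"):
            MetaModel.load(path)


class TestScreening:
    def test_full_library_is_a_permutation(self, smiles_model):
        model, _, ds = smiles_model
        lib = ds.smiles[:20]
        ranked = screen_library(model, lib, top_n=len(lib))
        assert sorted(ranked["smiles"]) == sorted(lib)
        assert list(ranked["rank"]) == list(range(1, 21))
        proba = ranked["probability"].to_numpy()
        assert np.all(np.diff(proba) <= 0)

    def test_identical_compounds_rank_adjacent_in_input_order(
        self, smiles_model
    ):
        model, _, ds = smiles_model
        smi = ds.smiles[3]
        ranked = screen_library(model, [ds.smiles[0], smi, ds.smiles[1], smi])
        pos = ranked.index[ranked["smiles"] == smi].tolist()
        assert pos[1] == pos[0] + 1

    def test_top_n_beyond_size_warns_and_returns_all(self, smiles_model):
        model, _, ds = smiles_model
        with pytest.warns(UserWarning, match="library size"):
            ranked = screen_library(model, ds.smiles[:5], top_n=50)
        assert len(ranked) == 5

    def test_known_active_analog_outranks_median(self, smiles_model):
        from chemstack import SyntheticSpec, generate_smiles_dataset

        model, _, _ = smiles_model
        above = 0
        for seed in range(5):
            lib = generate_smiles_dataset(
                SyntheticSpec(n_active=5, n_inactive=45, marker_effect=1.0,
                              label_noise=0.0, seed=200 + seed)
            )
            ranked = screen_library(model, lib.smiles)
            labels = {r.smiles: r.label for r in lib.records}
            ranks_of_actives = [
                row.rank for row in ranked.itertuples()
                if labels[row.smiles] == "active"
            ]
            if np.median(ranks_of_actives) < len(ranked) / 2:
                above += 1
        assert above >= 4
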
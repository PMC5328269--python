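"""Strong-classifier training: decoding, validation selection, bias, maps."""

import numpy as np
import pandas as pd
import pytest

import annealboost as ab
from annealboost.synthetic import _abstract_stumps
from conftest import random_ensemble


def table_from_matrix(X, y=None):
    cols = [f"f{i}" for i in range(X.shape[1])]
    return ab.FeatureTable(features=pd.DataFrame(X, columns=cols), labels=y)


def make_pool(spin_rows, energies, reads_each=1):
    rows = np.asarray(spin_rows, dtype=np.int8)
    return ab.SolutionPool(
        configs=rows,
        energies=np.asarray(energies, dtype=float),
        multiplicities=np.full(len(rows), reads_each),
        n_reads=reads_each * len(rows),
        method="exact",
        seed=0,
    )


def stump_ensemble_from_table(table, n_keep=None):
    cands = ab.enumerate_stumps(table)
    ens = ab.filter_random_guessers(cands, table)
    if n_keep is not None and ens.n > n_keep:
        ens = ab.WeakEnsemble.from_stumps(ens.stumps[:n_keep], table.matrix())
    return ens


class TestDecode:
    def test_all_negative_spins_empty_classifier(self):
        ens, _ = random_ensemble(4, 10, seed=0)
        pool = make_pool([[-1, -1, -1, -1]], [0.0])
        (clf,) = ab.decode_solutions(pool, ens)
        assert clf.is_empty and clf.cardinality == 0

    def test_all_positive_spins_full_vote(self):
        ens, _ = random_ensemble(4, 10, seed=1)
        pool = make_pool([[1, 1, 1, 1]], [0.0])
        (clf,) = ab.decode_solutions(pool, ens)
        assert clf.cardinality == 4

    def test_weights_are_shifted_spins(self):
        ens, _ = random_ensemble(5, 10, seed=2)
        spins = np.array([1, -1, 1, -1, -1])
        pool = make_pool([spins], [1.5])
        (clf,) = ab.decode_solutions(pool, ens)
        np.testing.assert_array_equal(clf.weights, (spins + 1) // 2)
        assert clf.energy == 1.5


class TestValidationSelect:
    def _stumps_on_features(self, X, y, k):
        table = table_from_matrix(X, y)
        cands = ab.enumerate_stumps(table)
        ens = ab.filter_random_guessers(cands, table)
        return table, ab.WeakEnsemble.from_stumps(ens.stumps[:k], table.matrix())

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(0)
        y = rng.choice([-1, 1], 40)
        X = np.column_stack([y * rng.uniform(0.5, 1, 40), rng.normal(size=40)])
        table, ens = self._stumps_on_features(X, y, 2)
        pool = make_pool([[1, 1]], [0.0])
        cands = ab.decode_solutions(pool, ens)
        assert ab.validation_select(cands, table) is cands[0]

    def test_lower_validation_error_beats_lower_energy(self):
        """The energy/error inversion: the minimal-energy solution need not have
        minimal validation error, and post-validation picks the latter."""
        rng = np.random.default_rng(1)
        y = rng.choice([-1, 1], 60)
        good = y.astype(float) * rng.uniform(0.5, 1.5, 60)
        noise = rng.normal(size=60)
        table, ens = self._stumps_on_features(np.column_stack([good, noise]), y, 3)
        # candidate A (lower energy) votes with noise stumps only; candidate
        # B includes the separating stump
        errs = [s.error for s in ens.stumps]
        best_stump = int(np.argmin(errs))
        wA = np.zeros(3, dtype=int)
        wA[[i for i in range(3) if i != best_stump][0]] = 1
        wB = np.zeros(3, dtype=int)
        wB[best_stump] = 1
        pool = make_pool(
            [2 * wA - 1, 2 * wB - 1], [-10.0, -5.0]
        )  # A has the lower energy
        cands = ab.decode_solutions(pool, ens)
        chosen = ab.validation_select(cands, table)
        np.testing.assert_array_equal(chosen.weights, wB)
        assert chosen.energy == -5.0

    def test_validation_tie_broken_by_energy(self):
        rng = np.random.default_rng(3)
        y = rng.choice([-1, 1], 30)
        # two duplicated stumps on identical feature columns: selecting
        # either one gives the same predictions, so validation error ties
        # and the lower-energy candidate must win
        ens = ab.WeakEnsemble(_abstract_stumps(2), np.vstack([y, y]).astype(np.int8))
        pool = make_pool([[1, -1], [-1, 1]], [2.0, 1.0])
        cands = ab.decode_solutions(pool, ens)
        X = np.column_stack([y, y]).astype(float)  # stump i predicts sign(x_i)
        chosen = ab.validation_select(cands, table_from_matrix(X, y))
        assert chosen.energy == 1.0

    def test_empty_candidates_error(self):
        table = table_from_matrix(np.zeros((4, 1)), np.array([1, 1, -1, -1]))
        with pytest.raises(ValueError):
            ab.validation_select([], table)


class TestBias:
    def _constant_classifier(self, outputs):
        """A classifier over one planted stump with fixed +/-1 outputs."""
        n = len(outputs)
        X = np.asarray(outputs, dtype=float)[:, None]
        stump = ab.Stump("linear", 0, None, "+", 0.0, 0.25)
        clf = ab.StrongClassifier(weights=np.array([1]), stumps=[stump])
        return clf, X

    def test_balanced_outputs_zero_bias(self):
        outputs = np.array([1.0, -1, 1, -1] * 5)
        clf, X = self._constant_classifier(outputs)
        y = np.array([1, -1] * 10)
        table = table_from_matrix(X, y)
        assert ab.set_bias(clf, table).bias == pytest.approx(0.0)

    def test_sixty_percent_positive_gives_point_two(self):
        outputs = np.concatenate([np.ones(60), -np.ones(40)])
        clf, X = self._constant_classifier(outputs)
        y = np.concatenate([np.ones(50, int), -np.ones(50, int)])
        table = table_from_matrix(X, y)
        assert ab.set_bias(clf, table).bias == pytest.approx(0.2)

    def test_majority_class_subsampled_for_balance(self):
        outputs = np.ones(100)
        clf, X = self._constant_classifier(outputs)
        y = np.concatenate([np.ones(80, int), -np.ones(20, int)])
        table = table_from_matrix(X, y)
        # the bias-set mean uses 20+20 samples regardless of imbalance
        assert ab.set_bias(clf, table, seed=1).bias == pytest.approx(1.0)

    def test_bias_reduces_error_of_skewed_classifier(self):
        """A classifier voting positive too often is corrected by B on a
        balanced evaluation set."""
        rng = np.random.default_rng(4)
        T = 400
        y = np.concatenate([np.ones(T // 2, int), -np.ones(T // 2, int)])
        x = y + rng.normal(size=T)  # informative but noisy feature
        X = x[:, None]
        stump = ab.Stump("linear", 0, None, "+", -0.8, 0.3)  # skewed threshold
        clf = ab.StrongClassifier(weights=np.array([1]), stumps=[stump])
        table = table_from_matrix(X, y)
        before = ab.evaluate(clf, table)["error"]
        clf_b = ab.set_bias(clf, table, seed=0)
        after = ab.evaluate(clf_b, table)["error"]
        assert after <= before

    def test_empty_classifier_warns_zero_bias(self):
        clf = ab.StrongClassifier(weights=np.array([0]), stumps=[
            ab.Stump("linear", 0, None, "+", 0.0, 0.4)
        ])
        table = table_from_matrix(np.zeros((4, 1)), np.array([1, -1, 1, -1]))
        with pytest.warns(UserWarning):
            assert ab.set_bias(clf, table).bias == 0.0


class TestPredictEvaluate:
    def test_empty_classifier_sign_convention(self):
        clf = ab.StrongClassifier(weights=np.array([0]), stumps=[
            ab.Stump("linear", 0, None, "+", 0.0, 0.4)
        ])
        table = table_from_matrix(np.zeros((5, 1)))
        np.testing.assert_array_equal(ab.predict(clf, table), np.ones(5))

    def test_single_stump_equivalence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 1))
        stump = ab.Stump("linear", 0, None, "+", 0.1, 0.2)
        clf = ab.StrongClassifier(weights=np.array([1]), stumps=[stump])
        np.testing.assert_array_equal(
            ab.predict(clf, table_from_matrix(X)), stump.predict(X)
        )

    def test_majority_vote_oracle_nine_stumps(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 9))
        stumps = [
            ab.Stump("linear", i, None, "+", float(rng.normal()), 0.3)
            for i in range(9)
        ]
        clf = ab.StrongClassifier(weights=np.ones(9, dtype=int), stumps=stumps)
        got = ab.predict(clf, table_from_matrix(X))
        votes = np.sum([s.predict(X) for s in stumps], axis=0)
        np.testing.assert_array_equal(got, np.where(votes >= 0, 1, -1))

    def test_perfect_and_inverted_evaluation(self):
        rng = np.random.default_rng(7)
        y = rng.choice([-1, 1], 40)
        X = y.astype(float)[:, None]
        stump = ab.Stump("linear", 0, None, "+", 0.0, 0.0)
        clf = ab.StrongClassifier(weights=np.array([1]), stumps=[stump])
        table = table_from_matrix(X, y)
        assert ab.evaluate(clf, table)["error"] == 0.0
        inv = table_from_matrix(X, -y)
        assert ab.evaluate(clf, inv)["error"] == 1.0

    def test_random_classifier_near_half_error(self):
        rng = np.random.default_rng(8)
        T = 10_000
        y = rng.choice([-1, 1], T)
        X = rng.normal(size=(T, 1))  # feature independent of labels
        stump = ab.Stump("linear", 0, None, "+", 0.0, 0.5)
        clf = ab.StrongClassifier(weights=np.array([1]), stumps=[stump])
        err = ab.evaluate(clf, table_from_matrix(X, y))["error"]
        assert err == pytest.approx(0.5, abs=0.02)

    def test_confusion_counts_sum(self):
        rng = np.random.default_rng(9)
        y = rng.choice([-1, 1], 30)
        X = rng.normal(size=(30, 1))
        stump = ab.Stump("linear", 0, None, "+", 0.0, 0.5)
        clf = ab.StrongClassifier(weights=np.array([1]), stumps=[stump])
        m = ab.evaluate(clf, table_from_matrix(X, y))
        assert m["tp"] + m["tn"] + m["fp"] + m["fn"] == 30


class TestClassifyRaster:
    def test_round_trip_equals_predict_on_extracted_table(self, small_scene):
        catalog = ab.default_catalog()[:10]
        table = ab.extract_feature_table(small_scene, catalog=catalog)
        cands = ab.enumerate_stumps(table)
        ens = ab.filter_random_guessers(cands, table)
        clf = ab.StrongClassifier(
            weights=np.ones(min(3, ens.n), dtype=int),
            stumps=ens.stumps[: min(3, ens.n)],
        )
        label_map = ab.classify_raster(clf, small_scene, catalog=catalog)
        direct = ab.predict(clf, table)
        np.testing.assert_array_equal(label_map.ravel(), direct)

    def test_empty_classifier_uniform_positive_map(self, small_scene):
        catalog = ["ndvi"]
        clf = ab.StrongClassifier(
            weights=np.array([0]),
            stumps=[ab.Stump("linear", 0, None, "+", 0.0, 0.4)],
        )
        label_map = ab.classify_raster(clf, small_scene, catalog=catalog)
        assert (label_map == 1).all()


class TestAlphaParsing:
    @pytest.mark.parametrize(
        "expr,n,expected",
        [("N/4", 108, 27.0), ("N*0.2", 10, 2.0), ("2.5", 4, 2.5), (7, 4, 7.0)],
    )
    def test_expressions(self, expr, n, expected):
        assert ab.parse_alpha(expr, n) == pytest.approx(expected)

    def test_rejects_nonpositive_and_garbage(self):
        with pytest.raises(ValueError):
            ab.parse_alpha("-N", 4)
        with pytest.raises(ValueError):
            ab.parse_alpha("import os", 4)


class TestTrainingPipeline:
    def _planted(self, seed=5):
        spec = ab.PlantedEnsembleSpec(
            n_stumps=12,
            n_samples=200,
            planted=(0, 1, 2, 3),
            correlation_blocks=((4, 5, 6, 7),),
            seed=seed,
        )
        return ab.generate_planted_ensemble(spec)

    def _validation_table(self, pe):
        # abstract ensembles carry no feature columns; evaluation uses the
        # training outputs as a stand-in validation set
        X = pe.ensemble.signs.T.astype(float)
        stumps = [
            ab.Stump("linear", i, None, "+", 0.0, 0.4)
            for i in range(pe.ensemble.n)
        ]
        ens = ab.WeakEnsemble.from_stumps(stumps, X)
        np.testing.assert_array_equal(ens.signs, pe.ensemble.signs)
        return table_from_matrix(X, pe.labels), ens

    def test_alpha_to_zero_selects_field_signs(self):
        """Field-dominated limit: at alpha -> 0 the optimum is s = sign(h)
        spin by spin, i.e. the individually best-correlated stumps."""
        pe = self._planted()
        table, ens = self._validation_table(pe)
        prob = ab.build_ising(pe.ensemble, pe.labels, f=pe.f_star)
        emb = ab.greedy_embed(prob, ab.chimera_graph(2, 2, 4))
        low = ab.renormalize(prob, emb, alpha=1e-9)
        optima, _ = ab.brute_force(low)
        np.testing.assert_array_equal(
            optima[0], np.sign(prob.h).astype(np.int8)
        )

    def test_one_cell_scan_equals_train_once(self):
        pe = self._planted()
        table, ens = self._validation_table(pe)
        config = ab.TrainConfig(
            alpha_grid=("1.0",), f_grid=(pe.f_star,), n_reads=4,
            solver="exact", seed=3,
        )
        best, surface, emb = ab.metaparameter_scan(
            ens, pe.labels, table, config, graph=None
        )
        assert len(surface) == 1
        single = ab.train_once(
            ens, pe.labels, table, f=pe.f_star, alpha=1.0, embedding=None,
            n_reads=4, solver="exact", seed=0,
        )
        np.testing.assert_array_equal(best.weights, single.weights)

    def test_planted_scan_beats_best_stump(self):
        pe = self._planted()
        table, ens = self._validation_table(pe)
        config = ab.TrainConfig(
            alpha_grid=("1.0",),
            f_grid=tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
            n_reads=4,
            solver="exact",
            seed=3,
        )
        best, _, _ = ab.metaparameter_scan(ens, pe.labels, table, config)
        best_stump_error = min(
            float(np.mean(row != pe.labels)) for row in pe.ensemble.signs
        )
        assert best.validation_error <= best_stump_error

    def test_retained_cardinality_non_increasing_in_f_exact(self):
        pe = self._planted(seed=9)
        table, ens = self._validation_table(pe)
        cards = []
        for f in np.linspace(0.0, 1.2, 9):
            prob = ab.build_ising(ens, pe.labels, f=float(f))
            optima, _ = ab.brute_force(prob)
            cards.append(int(ab.spins_to_weights(optima[0]).sum()))
        assert all(a >= b for a, b in zip(cards, cards[1:]))

    def test_full_scan_deterministic_given_master_seed(self):
        pe = self._planted(seed=11)
        table, ens = self._validation_table(pe)
        config = ab.TrainConfig(
            alpha_grid=("N/4", "N"), f_grid=(0.3, 0.6), n_reads=20,
            solver="sa", seed=21,
        )
        g = ab.chimera_graph(2, 2, 4)
        b1, s1, _ = ab.metaparameter_scan(ens, pe.labels, table, config, graph=g)
        b2, s2, _ = ab.metaparameter_scan(ens, pe.labels, table, config, graph=g)
        pd.testing.assert_frame_equal(s1, s2)
        np.testing.assert_array_equal(b1.weights, b2.weights)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        stumps = [
            ab.Stump("linear", 0, None, "+", 0.5, 0.2),
            ab.Stump("quadratic", 1, 2, "-", -0.25, 0.3),
        ]
        clf = ab.StrongClassifier(
            weights=np.array([1, 0]), stumps=stumps, bias=0.1,
            alpha=27.0, f=0.76, energy=-3.5, validation_error=0.09,
            solver="sa", seed=42,
        )
        path = tmp_path / "model.json"
        clf.to_json(path)
        back = ab.StrongClassifier.from_json(path)
        np.testing.assert_array_equal(back.weights, clf.weights)
        assert back.bias == 0.1 and back.alpha == 27.0 and back.f == 0.76
        assert back.stumps[1].kind == "quadratic"
        assert (back.stumps[1].i, back.stumps[1].j) == (1, 2)

class TestSplitTable:
    def test_proportional_scaling_and_disjointness(self, small_table):
        tr, va, bi = ab.split_table(small_table, seed=4)
        n = len(small_table)
        assert len(tr) + len(va) + len(bi) <= n
        # nominal 24000/3000/3000 proportions: 80% / 10% / 10%
        assert len(tr) == pytest.approx(0.8 * n, abs=2)
        assert len(va) == pytest.approx(0.1 * n, abs=2)
        coords = np.vstack([t.block_coords for t in (tr, va, bi)])
        assert len(np.unique(coords, axis=0)) == len(coords)

    def test_deterministic_given_seed(self, small_table):
        a = ab.split_table(small_table, seed=9)[0]
        b = ab.split_table(small_table, seed=9)[0]
        np.testing.assert_allclose(a.matrix(), b.matrix())
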
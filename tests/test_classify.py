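"""Classifier benchmarks: ROC-AUC, Tanimoto baseline, CV machinery, sweeps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import npek
from npek.classify import _chi2_top_k
from npek.fingerprints import VARIANT_COUNT_UNFOLDED


def brute_force_auc(scores, labels):
    """Independent oracle: pairwise concordance with ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert npek.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert npek.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        # 3 concordant of the 4 positive-negative pairs
        assert npek.roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_single_class_undefined(self):
        with pytest.raises(npek.UndefinedMetricError):
            npek.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_all_small_inputs(self):
        # all label patterns of size <= 8 with both classes, fixed score grid
        rng = np.random.default_rng(0)
        for n in range(2, 9):
            scores = rng.choice([0.1, 0.2, 0.2, 0.5, 0.9], size=n)
            for bits in range(1, 2**n - 1):
                labels = [(bits >> i) & 1 for i in range(n)]
                assert npek.roc_auc(scores, labels) == pytest.approx(
                    brute_force_auc(scores, labels)
                )

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complement_property_for_tie_free_scores(self, raw):
        scores = list(dict.fromkeys(raw))  # dedupe -> tie-free
        if len(scores) < 4:
            return
        labels = [i % 2 for i in range(len(scores))]
        assert npek.roc_auc(scores, labels) + npek.roc_auc(
            [-s for s in scores], labels
        ) == pytest.approx(1.0)


class TestDummyLabels:
    def test_positive_count_preserved_and_deterministic(self):
        labels = [True] * 5 + [False] * 45
        out1 = npek.make_dummy_labels(labels, seed=3)
        out2 = npek.make_dummy_labels(labels, seed=3)
        assert out1.sum() == 5 and np.array_equal(out1, out2)

    def test_each_index_positive_at_hypergeometric_rate(self):
        labels = [True] * 5 + [False] * 45
        freq = np.zeros(50)
        n_seeds = 400
        for seed in range(n_seeds):
            freq += npek.make_dummy_labels(labels, seed=seed)
        freq /= n_seeds
        # P(index positive) = 5/50 = 0.1; binomial sd ~ 0.015
        assert np.all(np.abs(freq - 0.1) < 0.06)


def _fp(counts):
    return npek.SparseCountFingerprint(counts, npek.CLASSIFIER_PARAMS)


class TestCountTanimoto:
    def test_identical_is_one(self):
        a = _fp({1: 2, 7: 3})
        assert npek.count_tanimoto(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert npek.count_tanimoto(_fp({1: 2}), _fp({2: 2})) == 0.0

    def test_worked_example(self):
        # sum(min)/sum(max) = (1+1)/(2+1)
        assert npek.count_tanimoto(_fp({1: 2, 2: 1}), _fp({1: 1, 2: 1})) == pytest.approx(2 / 3)

    def test_params_mismatch_rejected(self):
        other = npek.FingerprintParams(radius=2, chiral=True, variant=VARIANT_COUNT_UNFOLDED)
        with pytest.raises(npek.ParameterError):
            npek.count_tanimoto(_fp({1: 1}), npek.SparseCountFingerprint({1: 1}, other))

    @given(
        st.dictionaries(st.integers(0, 30), st.integers(1, 9), max_size=10),
        st.dictionaries(st.integers(0, 30), st.integers(1, 9), max_size=10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetric_bounded_and_matches_naive_formula(self, ca, cb):
        a, b = _fp(ca), _fp(cb)
        s = npek.count_tanimoto(a, b)
        assert s == npek.count_tanimoto(b, a)
        assert 0.0 <= s <= 1.0
        keys = set(ca) | set(cb)
        num = sum(min(ca.get(k, 0), cb.get(k, 0)) for k in keys)
        den = sum(max(ca.get(k, 0), cb.get(k, 0)) for k in keys)
        assert s == pytest.approx(num / den if den else 0.0)
        if den:
            assert (s == 1.0) == (ca == cb)


class TestSimilarityScores:
    def test_identity_reference_scores_one(self):
        q = _fp({1: 1, 2: 2})
        assert npek.similarity_scores([q], [q, _fp({5: 1})]) == [1.0]

    def test_max_over_references(self):
        q = _fp({1: 2, 2: 2})
        refs = [_fp({1: 1}), _fp({1: 2, 2: 1}), _fp({2: 2})]
        pair = [npek.count_tanimoto(q, r) for r in refs]
        assert npek.similarity_scores([q], refs) == [max(pair)]

    def test_self_exclusion_in_cv_mode(self):
        q = _fp({1: 1})
        other = _fp({1: 1, 2: 5})
        scores = npek.similarity_scores([q], [q, other], exclude_self=True)
        assert scores[0] == npek.count_tanimoto(q, other) < 1.0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(npek.EmptySetError):
            npek.similarity_scores([_fp({1: 1})], [])


class TestSelectTopFeatures:
    def test_k_equals_n_features_keeps_all(self, separable_matrix):
        fm, y = separable_matrix
        out = npek.select_top_features(fm, y, fm.n_features)
        assert set(out.feature_ids) == set(fm.feature_ids)

    def test_planted_discriminative_column_ranked_first(self):
        rng = np.random.default_rng(2)
        y = np.array([True] * 10 + [False] * 30)
        noise = rng.integers(0, 4, size=(40, 5))
        signal = np.where(y, 8, 0)[:, None]
        counts = np.hstack([noise[:, :2], signal, noise[:, 2:]])
        fm = npek.FeatureMatrix([f"m{i}" for i in range(40)], np.arange(6),
                                counts, npek.CLASSIFIER_PARAMS)
        out = npek.select_top_features(fm, y, 1)
        assert list(out.feature_ids) == [2]

    def test_matches_exhaustive_chi2_ranking(self):
        from scipy.stats import chi2 as chi2_dist
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 5, size=(20, 3))
        y = np.array([True] * 8 + [False] * 12)
        fm = npek.FeatureMatrix([f"m{i}" for i in range(20)], np.arange(3),
                                counts, npek.CLASSIFIER_PARAMS)
        # brute-force oracle: compute the statistic per column from first principles
        stats = []
        for j in range(3):
            o_pos, o_neg = counts[y, j].sum(), counts[~y, j].sum()
            tot = o_pos + o_neg
            e_pos, e_neg = tot * 8 / 20, tot * 12 / 20
            stats.append((o_pos - e_pos) ** 2 / e_pos + (o_neg - e_neg) ** 2 / e_neg)
        expect = sorted(np.argsort(-np.array(stats), kind="stable")[:2])
        out = npek.select_top_features(fm, y, 2)
        assert list(out.feature_ids) == expect

    def test_k_out_of_range(self, separable_matrix):
        fm, y = separable_matrix
        with pytest.raises(npek.ParameterError):
            npek.select_top_features(fm, y, fm.n_features + 1)


class TestCrossValidate:
    def test_rf_separates_planted_signal(self, separable_matrix):
        fm, y = separable_matrix
        res = npek.cross_validate(npek.ModelSpec.rf(), fm, y, npek.CVConfig(seed=1))
        assert res.mean_auc > 0.95
        assert len(res.per_fold_auc) == 15

    def test_dummy_rf_near_chance(self, separable_matrix):
        fm, y = separable_matrix
        res = npek.cross_validate(npek.ModelSpec.dummy_rf(), fm, y, npek.CVConfig(seed=1))
        assert 0.4 <= res.mean_auc <= 0.6

    def test_similarity_baseline_separates(self, separable_matrix):
        fm, y = separable_matrix
        res = npek.cross_validate(npek.ModelSpec.similarity(), fm, y, npek.CVConfig(seed=1))
        assert res.mean_auc > 0.9

    def test_all_negative_labels_infeasible(self, separable_matrix):
        fm, _ = separable_matrix
        with pytest.raises(npek.InfeasibleCVError):
            npek.cross_validate(npek.ModelSpec.rf(), fm, [False] * fm.n_molecules,
                                npek.CVConfig(seed=1))

    def test_stratified_fold_positive_counts_balanced(self):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([True] * 13 + [False] * 52)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        fold_pos = [y[test].sum() for _, test in skf.split(np.zeros((65, 1)), y)]
        assert max(fold_pos) - min(fold_pos) <= 1

    def test_deterministic_given_seed(self, separable_matrix):
        fm, y = separable_matrix
        cv = npek.CVConfig(seed=9)
        r1 = npek.cross_validate(npek.ModelSpec.rf(), fm, y, cv)
        r2 = npek.cross_validate(npek.ModelSpec.rf(), fm, y, cv)
        assert r1.per_fold_auc == r2.per_fold_auc

    def test_knn_and_nn_run(self, separable_matrix):
        fm, y = separable_matrix
        for spec in (npek.ModelSpec.knn(), npek.ModelSpec.nn(max_epochs=30)):
            res = npek.cross_validate(spec, fm, y, npek.CVConfig(n_repeats=1, seed=2))
            assert 0.0 <= res.mean_auc <= 1.0


class TestFeatureSetSweep:
    def test_sweep_table_shape_and_null_row(self, separable_matrix):
        fm, y = separable_matrix
        cv = npek.CVConfig(n_repeats=1, seed=3)
        specs = [npek.ModelSpec.rf(), npek.ModelSpec.dummy_rf(), npek.ModelSpec.similarity()]
        table = npek.feature_set_sweep(fm, y, cv, specs, k_grid=[1, 4, fm.n_features])
        assert len(table) == 9
        dummy = table[table.model == "dummy_rf"]
        assert ((dummy.mean_auc - 0.5).abs() < 0.25).all()
        # similarity baseline is k-independent
        sim = table[table.model == "similarity"].mean_auc
        assert sim.nunique() == 1

    def test_full_grid_matches_single_run(self, separable_matrix):
        fm, y = separable_matrix
        cv = npek.CVConfig(n_repeats=1, seed=4)
        table = npek.feature_set_sweep(fm, y, cv, [npek.ModelSpec.rf()], k_grid=[fm.n_features])
        single = npek.cross_validate(npek.ModelSpec.rf(), fm, y, cv,
                                     select_k=fm.n_features)
        assert table.mean_auc.iloc[0] == pytest.approx(single.mean_auc)

    def test_auc_plateaus_with_redundant_features(self, separable_matrix):
        fm, y = separable_matrix
        cv = npek.CVConfig(n_repeats=1, seed=5)
        table = npek.feature_set_sweep(fm, y, cv, [npek.ModelSpec.rf()],
                                       k_grid=[2, 8, fm.n_features])
        aucs = table.mean_auc.to_numpy()
        assert aucs[-1] >= aucs[0] - 0.05
        assert abs(aucs[-1] - aucs[-2]) < 0.1


class TestRadiusChiralityBenchmark:
    def test_ring_context_signal_needs_radius(self):
        # positives carry the chain para to the ring methyl, negatives ortho:
        # an attachment-pattern signal with identical atom composition, so it
        # is invisible to radius-0 environments.  Terminal decorations are
        # rotated between classes so they carry no class signal either.
        terms = ["O", "N", "F", "Cl", "OC"] * 2
        pos = [f"Cc1ccc({'C' * n}{terms[i]})cc1" for i, n in enumerate(range(2, 12))]
        neg = [f"Cc1ccccc1{'C' * n}{terms[(i + 1) % 10]}" for i, n in enumerate(range(2, 12))]
        mols = [npek.parse_smiles(s, mol_id=f"p{i}", source="epitope", label_b=True)
                for i, s in enumerate(pos)]
        mols += [npek.parse_smiles(s, mol_id=f"n{i}") for i, s in enumerate(neg)]
        y = [True] * 10 + [False] * 10
        table = npek.radius_chirality_benchmark(
            mols, y, radii=[0, 3], chiral_options=[False],
            cv=npek.CVConfig(n_repeats=1, n_folds=2, seed=0), min_occurrence=3,
        )
        auc0 = table[table.radius == 0].mean_auc.iloc[0]
        auc3 = table[table.radius == 3].mean_auc.iloc[0]
        assert auc3 > auc0
        assert set(table.radius) == {0, 3}

    def test_chirality_toggle_invariant_for_achiral_sets(self, separable_set):
        mols = separable_set.molecules[120:]  # 30 background + 25 positives
        y = [m.label_b for m in mols]
        assert sum(y) >= 3
        table = npek.radius_chirality_benchmark(
            mols, y, radii=[2], chiral_options=[False, True],
            cv=npek.CVConfig(n_repeats=1, n_folds=3, seed=1), min_occurrence=5,
        )
        aucs = table.mean_auc.to_numpy()
        assert aucs[0] == pytest.approx(aucs[1], abs=1e-9)
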
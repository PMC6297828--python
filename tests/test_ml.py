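"""Classification pipeline: perturbation moments, LOOCV, selection,
ensembles and ROC behaviour on constructed data."""

import numpy as np
import pandas as pd
import pytest

from tcranet.clustering import ActivityMatrix
from tcranet.errors import ConfigurationError, ValidationError
from tcranet import ml
from tcranet.io import SampleMeta


def make_fm(X, y, positive="b"):
    n = X.shape[0]
    index = pd.MultiIndex.from_tuples(
        [(f"S{i:03d}", 1) for i in range(n)], names=["sample_id", "time_point"]
    )
    Xdf = pd.DataFrame(np.asarray(X, float), index=index,
                       columns=list(range(X.shape[1])))
    ydf = pd.Series(["b" if v else "a" for v in y], index=index)
    return ml.FeatureMatrix(Xdf, ydf, positive)


def blobs(rng, n_per_class=20, n_features=2, shift=10.0):
    X0 = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X1 = rng.normal(0.0, 1.0, (n_per_class, n_features))
    X1[:, 0] += shift
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestPerturb:
    def test_sigma_zero_is_identity(self, rng):
        X = rng.lognormal(0, 1, (10, 4))
        out = ml.perturb(X, 0.0, rng)
        np.testing.assert_array_equal(out, X)

    def test_mean_preserved(self, rng):
        vals = ml.perturb(np.ones(10_000), 0.25, rng)
        assert vals.mean() == pytest.approx(1.0, abs=0.01)

    def test_coefficient_of_variation_matches_sigma(self, rng):
        vals = ml.perturb(np.ones(10_000), 0.1, rng)
        assert vals.std(ddof=1) == pytest.approx(0.1, abs=0.005)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ml.perturb(np.ones(3), -0.1)

    def test_dataframe_round_trip_type(self, rng):
        df = pd.DataFrame(np.ones((3, 2)))
        out = ml.perturb(df, 0.05, rng)
        assert isinstance(out, pd.DataFrame)


class TestLoocvScore:
    def test_separated_blobs_near_perfect(self, rng):
        X, y = blobs(rng)
        assert ml.loocv_score(X, y) >= 0.95

    def test_permuted_labels_near_chance(self, rng):
        X, y = blobs(rng)
        scores = []
        for _ in range(20):
            perm = rng.permutation(y)
            if len(np.unique(perm)) < 2:
                continue
            scores.append(ml.loocv_score(X, perm))
        assert np.mean(scores) == pytest.approx(0.5, abs=0.15)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            ml.loocv_score(np.ones((4, 2)), np.zeros(4))

    def test_one_point_per_class_defined(self):
        # every fold leaves a single-class training set; result defined, no crash
        score = ml.loocv_score(np.array([[0.0], [1.0]]), np.array([0, 1]))
        assert 0.0 <= score <= 1.0

    def test_deterministic(self, rng):
        X, y = blobs(rng, shift=2.0)
        assert ml.loocv_score(X, y) == ml.loocv_score(X, y)


class TestForwardSelection:
    def test_planted_pair_recovered(self, rng):
        # complementary signal: each informative feature separates half the
        # positive class, so only the pair attains a near-perfect score
        n = 40
        X = rng.normal(size=(n, 22))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        pos = np.flatnonzero(y == 1)
        X[pos[: len(pos) // 2], 3] += 4.0
        X[pos[len(pos) // 2 :], 11] += 4.0
        fm = make_fm(X, y)
        result = ml.forward_selection(fm, ml.MLConfig(dims=(2, 2)))
        top_pair, top_score = result[2][0]
        assert set(top_pair) == {3, 11}
        assert top_score >= 0.9

    def test_top_k_larger_than_candidates_keeps_all(self, rng):
        X, y = blobs(rng, n_features=3)
        fm = make_fm(X, y)
        result = ml.forward_selection(fm, ml.MLConfig(top_k=50, dims=(2, 2)))
        assert len(result[2]) == 3  # C(3,2) pairs

    def test_extensions_deduplicate_as_sets(self, rng):
        X, y = blobs(rng, n_features=4, shift=3.0)
        fm = make_fm(X, y)
        result = ml.forward_selection(fm, ml.MLConfig(top_k=50, dims=(2, 3)))
        triples = [sub for sub, _ in result[3]]
        assert len(triples) == len({frozenset(t) for t in triples}) == 4  # C(4,3)

    def test_needs_two_features(self, rng):
        X, y = blobs(rng, n_features=1)
        with pytest.raises(ConfigurationError):
            ml.forward_selection(make_fm(X, y), ml.MLConfig())


class TestEnsemble:
    def test_m1_equals_single_machine(self, rng):
        X, y = blobs(rng, shift=3.0)
        fm = make_fm(X, y)
        ens = ml.train_ensemble(fm, [(0, 1)], ml.MLConfig(ensemble_size=1))
        single = ens.machines[0][1]
        expected = 1 / (1 + np.exp(-single.decision_function(fm.X.to_numpy(float))))
        np.testing.assert_allclose(ens.score(fm.X), expected)

    def test_duplicated_subsets_equal_single_machine(self, rng):
        X, y = blobs(rng, shift=3.0)
        fm = make_fm(X, y)
        with pytest.warns(UserWarning):
            one = ml.train_ensemble(fm, [(0, 1)], ml.MLConfig(ensemble_size=3))
        five = ml.train_ensemble(fm, [(0, 1)] * 3, ml.MLConfig(ensemble_size=3))
        np.testing.assert_allclose(one.score(fm.X), five.score(fm.X))

    def test_ensemble_variance_not_above_mean_member_variance(self, rng):
        """Averaging the committee reduces output variance across
        bootstrap-trained replicates."""
        n, f = 40, 6
        X = rng.normal(size=(n, f))
        y = np.array([0, 1] * (n // 2))
        X[y == 1] += 1.0
        subsets = [(i, j) for i in range(f) for j in range(i + 1, f)][:5]
        cfg = ml.MLConfig(ensemble_size=5)
        probe = make_fm(rng.normal(size=(10, f)) + 0.5, [0] * 10)
        ens_outputs, member_outputs = [], []
        for b in range(20):
            ix = rng.integers(0, n, n)
            if len(np.unique(y[ix])) < 2:
                continue
            fm_b = make_fm(X[ix], y[ix])
            ens = ml.train_ensemble(fm_b, subsets, cfg)
            ens_outputs.append(ens.score(probe.X))
            member_outputs.append(
                [ml.ClassifierEnsemble([m]).score(probe.X) for m in ens.machines]
            )
        ens_var = np.var(np.array(ens_outputs), axis=0).mean()
        member_var = np.var(np.array(member_outputs), axis=0).mean()
        assert ens_var <= member_var + 1e-12


class TestEvaluateRoc:
    def test_perfect_scorer_auc_one_at_sigma_zero(self, rng):
        X, y = blobs(rng, shift=10.0)
        fm = make_fm(X, y)
        cfg = ml.MLConfig(ensemble_size=1, noise_amplitudes=(0.0,))
        roc = ml.evaluate_roc(fm, {2: [((0, 1), 1.0)]}, cfg)
        assert roc.auc[(2, 0.0)] == pytest.approx(1.0)
        assert roc.chosen_dim == 2

    def test_random_scorer_auc_near_half(self):
        # n large enough that the leave-one-out class-prior artifact
        # (the held-out class is underrepresented) stays within tolerance
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(80, 2))
            y = np.array([0, 1] * 40)
            fm = make_fm(X, y)
            cfg = ml.MLConfig(ensemble_size=1, noise_amplitudes=(0.0,), seed=seed)
            roc = ml.evaluate_roc(fm, {2: [((0, 1), 0.5)]}, cfg)
            aucs.append(roc.auc[(2, 0.0)])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_noise_average_is_mean_over_amplitudes(self, rng):
        X, y = blobs(rng, shift=2.0)
        fm = make_fm(X, y)
        cfg = ml.MLConfig(ensemble_size=1, noise_amplitudes=(0.0, 0.1, 0.2))
        roc = ml.evaluate_roc(fm, {2: [((0, 1), 1.0)]}, cfg)
        expected = np.mean([roc.auc[(2, s)] for s in cfg.noise_amplitudes])
        assert roc.noise_avg_auc[2] == pytest.approx(expected)

    def test_tie_prefers_smaller_dimension(self, rng):
        X, y = blobs(rng, n_features=3, shift=10.0)
        fm = make_fm(X, y)
        cfg = ml.MLConfig(ensemble_size=1, noise_amplitudes=(0.0,))
        roc = ml.evaluate_roc(fm, {2: [((0, 1), 1.0)], 3: [((0, 1, 2), 1.0)]}, cfg)
        assert roc.chosen_dim == 2

    def test_single_class_errors(self, rng):
        X, _ = blobs(rng)
        fm = make_fm(X, np.zeros(X.shape[0], dtype=int))
        with pytest.raises(ValidationError):
            ml.evaluate_roc(fm, {2: [((0, 1), 1.0)]}, ml.MLConfig())


class TestActiveFeatureFilter:
    def _activity(self, active_counts, n_points=73):
        cols = pd.MultiIndex.from_tuples(
            [(f"S{i:02d}", 1 + i % 8) for i in range(n_points)],
            names=["sample_id", "time_point"],
        )
        rows = {}
        for ca, k in active_counts.items():
            vals = np.zeros(n_points)
            vals[:k] = 1.0
            rows[ca] = vals
        return ActivityMatrix(pd.DataFrame(rows, index=cols).T)

    def test_strict_95_percent_boundary_on_73_points(self):
        act = self._activity({0: 70, 1: 69, 2: 0})
        kept = ml.active_feature_filter(act, ml.MLConfig())
        assert kept == [0]  # 70/73 = 95.9% kept; 69/73 = 94.5% and all-zero dropped

    def test_empty_result_is_configuration_error(self):
        act = self._activity({0: 10})
        with pytest.raises(ConfigurationError, match="active_fraction"):
            ml.active_feature_filter(act, ml.MLConfig())


class TestTwoStage:
    def test_control_only_errors(self, rng):
        cols = pd.MultiIndex.from_tuples(
            [("C1", t) for t in range(1, 5)], names=["sample_id", "time_point"]
        )
        act = ActivityMatrix(
            pd.DataFrame(rng.lognormal(0, 1, (3, 4)), index=[0, 1, 2], columns=cols)
        )
        metas = [SampleMeta("C1", "control", {t: "healthy" for t in range(1, 5)})]
        with pytest.raises(ValidationError):
            ml.two_stage_classify(act, metas, ml.MLConfig(dims=(2, 2)))

    def test_stage2_skipped_without_cancer_class(self, rng):
        cols = pd.MultiIndex.from_tuples(
            [(s, t) for s in ("C1", "T1") for t in range(1, 7)],
            names=["sample_id", "time_point"],
        )
        X = rng.lognormal(0, 1, (3, 12))
        X[0, 6:] *= 6  # separable stage-1 signal
        act = ActivityMatrix(pd.DataFrame(X, index=[0, 1, 2], columns=cols))
        metas = [
            SampleMeta("C1", "control", {t: "healthy" for t in range(1, 7)}),
            SampleMeta("T1", "transgenic", {t: "healthy" for t in range(1, 7)}),
        ]
        with pytest.warns(UserWarning, match="stage 2 skipped"):
            out = ml.two_stage_classify(act, metas, ml.MLConfig(dims=(2, 2)))
        assert out.stage2 is None and out.feature_jaccard is None

    def test_end_to_end_determinism(self, benchmark):
        """Identical config and seed give identical selected subsets and
        identical ROC tables."""
        _, act = benchmark.truth_activity()
        # restrict to a small feature slice to keep the check fast
        ub = benchmark.truth.ubiquitous_ids[:10]
        act = ActivityMatrix(act.data.loc[ub])
        metas = benchmark.sample_metas()
        cfg = ml.MLConfig(dims=(2, 2), seed=11, active_fraction=0.8, ensemble_size=3)
        r1 = ml.two_stage_classify(act, metas, cfg)
        r2 = ml.two_stage_classify(act, metas, cfg)
        assert r1.stage1.subsets_by_dim == r2.stage1.subsets_by_dim
        assert r1.stage1.roc.auc == r2.stage1.roc.auc
        assert r1.stage1.selected_features == r2.stage1.selected_features
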
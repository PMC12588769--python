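import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from scalesdm.ensemble import (
    ALGORITHMS,
    BaseLearnerSpec,
    auc,
    boyce_index,
    build_ensemble,
    cross_validate,
    ensemble_weighted_mean,
    fit_base_learner,
    max_sss_threshold,
    response_curve,
    tss_at,
    tss_max,
    variable_importance,
)


def pair_auc(pos, neg):
    """Pair-enumeration oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


def exhaustive_max_sss(pos, neg):
    best_t, best_v = None, -np.inf
    for t in sorted(set(pos) | set(neg)):
        v = np.mean(np.asarray(pos) >= t) + np.mean(np.asarray(neg) < t) - 1.0
        if v > best_v + 1e-15:
            best_t, best_v = t, v
    return best_t, best_v


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_four_pair_enumeration(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_oracle_on_random_scores(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 50)).tolist()
        neg = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 50)).tolist()
        assert auc(pos, neg) == pytest.approx(pair_auc(pos, neg), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestTSSAndThreshold:
    def test_perfect_separation_tss_one(self):
        assert tss_at([0.9, 0.8], [0.2, 0.1], 0.5) == pytest.approx(1.0)

    def test_identical_distributions_tss_zero(self):
        for t in (0.1, 0.5, 0.9):
            assert tss_at([0.3, 0.7], [0.3, 0.7], t) == pytest.approx(0.0)

    def test_confusion_count_formula(self):
        # 8/10 presences above, 7/10 background below -> 0.8 + 0.7 - 1 = 0.5
        pos = [0.9] * 8 + [0.1] * 2
        neg = [0.2] * 7 + [0.8] * 3
        assert tss_at(pos, neg, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_max_sss_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed + 100)
        pos = rng.random(rng.integers(3, 50)).round(2).tolist()
        neg = rng.random(rng.integers(3, 50)).round(2).tolist()
        t0, v0 = exhaustive_max_sss(pos, neg)
        assert max_sss_threshold(pos, neg) == pytest.approx(t0)
        v, t = tss_max(pos, neg)
        assert v == pytest.approx(v0)

    def test_degenerate_tie_returns_smallest_candidate(self):
        scores = [0.2, 0.5, 0.8]
        assert max_sss_threshold(scores, scores) == 0.2


class TestBoyce:
    def test_monotone_concentration_gives_one(self):
        rng = np.random.default_rng(0)
        land = rng.uniform(0, 1, 5000)
        pres = rng.uniform(0, 1, 4000) ** 0.25  # mass increasing with score
        assert boyce_index(pres, land) == pytest.approx(1.0)

    def test_anti_monotone_gives_minus_one(self):
        rng = np.random.default_rng(1)
        land = rng.uniform(0, 1, 5000)
        pres = 1.0 - rng.uniform(0, 1, 4000) ** 0.25
        assert boyce_index(pres, land) == pytest.approx(-1.0)

    def test_null_presences_from_landscape_distribution(self):
        # presences drawn from the landscape law: P/E is flat, so the index
        # is a null Spearman over 10 classes (per-seed sd ~ 1/3); the sound
        # null property is a mean near zero across seeds
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            land = rng.uniform(0, 1, 4000)
            pres = rng.choice(land, size=500)
            vals.append(boyce_index(pres, land))
        assert abs(np.mean(vals)) < 0.25

    def test_undefined_when_too_few_classes(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert np.isnan(boyce_index([0.5], [0.5] * 10))


@pytest.fixture(scope="module")
def toy_features():
    rng = np.random.default_rng(7)
    n = 120
    Xp = pd.DataFrame(
        {"a": rng.normal(1.2, 1, n), "b": rng.normal(0.5, 1, n), "c": rng.normal(0, 1, n)}
    )
    Xb = pd.DataFrame(
        {"a": rng.normal(0, 1, 4 * n), "b": rng.normal(0, 1, 4 * n), "c": rng.normal(0, 1, 4 * n)}
    )
    return Xp, Xb


class TestBaseLearners:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_separable_toy_training_auc_is_one(self, algorithm):
        Xp = pd.DataFrame({"a": np.ones(30), "b": np.zeros(30)})
        Xb = pd.DataFrame({"a": np.zeros(60), "b": np.zeros(60)})
        scorer = fit_base_learner(BaseLearnerSpec(algorithm), Xp, Xb, seed=0)
        assert auc(scorer.predict(Xp), scorer.predict(Xb)) == 1.0

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_deterministic_given_seed(self, algorithm, toy_features):
        Xp, Xb = toy_features
        s1 = fit_base_learner(BaseLearnerSpec(algorithm), Xp, Xb, seed=5)
        s2 = fit_base_learner(BaseLearnerSpec(algorithm), Xp, Xb, seed=5)
        assert np.allclose(s1.predict(Xb), s2.predict(Xb), atol=1e-12)

    def test_null_labels_give_chance_auc(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 3))
            labels = np.zeros(300, dtype=bool)
            labels[rng.choice(300, 60, replace=False)] = True
            cols = list("abc")
            Xp = pd.DataFrame(X[labels], columns=cols)
            Xb = pd.DataFrame(X[~labels], columns=cols)
            # held-out evaluation on fresh null data from the same law
            scorer = fit_base_learner(BaseLearnerSpec("GLM"), Xp, Xb, seed=seed)
            Xte = rng.normal(size=(400, 3))
            s = scorer.predict(pd.DataFrame(Xte, columns=cols))
            aucs.append(auc(s[:100], s[100:]))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self, toy_features):
        Xp, _ = toy_features
        with pytest.raises(ValueError):
            fit_base_learner(BaseLearnerSpec("GLM"), Xp, Xp.iloc[:1])


class TestCrossValidate:
    def test_run_cardinality(self, toy_features):
        Xp, Xb = toy_features
        specs = [BaseLearnerSpec(a) for a in ("GLM", "RF")]
        runs = cross_validate(Xp, [Xb, Xb], specs, k=3, repeats=2, seed=0)
        # 2 algorithms x 2 PA sets x 2 repeats x 3 folds
        assert len(runs) == 2 * 2 * 2 * 3

    def test_folds_partition_presences_each_repeat(self, toy_features):
        Xp, Xb = toy_features
        runs = cross_validate(Xp, [Xb], [BaseLearnerSpec("GLM")], k=4, repeats=2, seed=1)
        # reconstruct fold membership through the same rng stream
        for rep in range(2):
            rng = np.random.default_rng([1, 0, rep])
            perm = rng.permutation(len(Xp))
            folds = [perm[i::4] for i in range(4)]
            assert sorted(np.concatenate(folds).tolist()) == list(range(len(Xp)))

    def test_k_larger_than_presences_rejected(self, toy_features):
        _, Xb = toy_features
        tiny = Xb.iloc[:3]
        with pytest.raises(ValueError):
            cross_validate(tiny, [Xb], [BaseLearnerSpec("GLM")], k=5)


class TestEnsembleWeighting:
    def test_single_member_identity(self):
        scores = np.array([0.1, 0.4, 0.9])
        out = ensemble_weighted_mean([scores], [0.9])
        assert np.array_equal(out, scores)

    def test_equal_auc_is_plain_mean(self):
        out = ensemble_weighted_mean(
            [np.array([0.2]), np.array([0.6])], [0.85, 0.85]
        )
        assert out[0] == pytest.approx(0.4)

    def test_hand_computed_weights_and_cutoff(self):
        scores = [np.array([1.0]), np.array([0.0]), np.array([0.5])]
        out = ensemble_weighted_mean(scores, [0.9, 0.8, 0.6], auc_cutoff=0.7)
        # third member excluded; weights 9/17 and 8/17
        assert out[0] == pytest.approx(9 / 17 * 1.0 + 8 / 17 * 0.0)

    def test_bounded_by_member_extrema(self):
        rng = np.random.default_rng(0)
        members = [rng.random(50) for _ in range(4)]
        aucs = [0.75, 0.8, 0.85, 0.9]
        out = ensemble_weighted_mean(members, aucs)
        stack = np.stack(members)
        assert np.all(out >= stack.min(axis=0) - 1e-12)
        assert np.all(out <= stack.max(axis=0) + 1e-12)

    def test_no_member_above_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ensemble_weighted_mean([np.array([0.5])], [0.6], auc_cutoff=0.7)

    def test_weights_sum_to_one(self, toy_features):
        Xp, Xb = toy_features
        runs = cross_validate(Xp, [Xb], [BaseLearnerSpec("GLM")], k=3, repeats=1, seed=2)
        model = build_ensemble(runs, Xp, Xb, auc_cutoff=0.0)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)


class _LinearScorer:
    """Deterministic stand-in model: score = clipped linear form."""

    def __init__(self, coef):
        self.coef = coef

    def predict(self, X):
        z = X.to_numpy(dtype=float) @ np.asarray(self.coef)
        return 1 / (1 + np.exp(-z))


class TestInterpretation:
    def test_unused_variable_has_zero_importance(self, toy_features):
        _, Xb = toy_features
        model = _LinearScorer([1.0, 0.5, 0.0])
        assert variable_importance(model, Xb, "c", seed=0) == pytest.approx(0.0, abs=1e-6)

    def test_single_variable_scorer_has_high_importance(self, toy_features):
        _, Xb = toy_features
        model = _LinearScorer([1.0, 0.0, 0.0])
        assert variable_importance(model, Xb, "a", seed=0) >= 0.9

    def test_importance_deterministic(self, toy_features):
        _, Xb = toy_features
        model = _LinearScorer([0.7, 0.3, 0.1])
        v1 = variable_importance(model, Xb, "a", seed=3)
        v2 = variable_importance(model, Xb, "a", seed=3)
        assert v1 == v2

    def test_response_curve_monotone_for_monotone_scorer(self, toy_features):
        _, Xb = toy_features
        model = _LinearScorer([1.0, 0.0, 0.0])
        curve = response_curve(model, Xb, "a", n_points=50)
        assert (np.diff(curve["score"]) >= -1e-12).all()

    def test_response_curve_endpoints_match_direct_evaluation(self, toy_features):
        _, Xb = toy_features
        model = _LinearScorer([0.4, -0.6, 0.2])
        curve = response_curve(model, Xb, "b", n_points=10)
        med = Xb.median()
        probe = pd.DataFrame([med, med])
        probe.loc[probe.index[0], "b"] = Xb["b"].min()
        probe.loc[probe.index[1], "b"] = Xb["b"].max()
        direct = model.predict(probe)
        assert curve["score"].iloc[0] == pytest.approx(direct[0])
        assert curve["score"].iloc[-1] == pytest.approx(direct[1])


@pytest.fixture(scope="module")
def fitted(landscape, suitability):
    import scalesdm as s
    from scalesdm.occurrences import sample_pseudo_absences
    from scalesdm.projection import extract_features, project_suitability

    occ = s.sample_occurrences(suitability, 200, seed=21)
    cells = occ.cells(landscape.reference)
    pa = sample_pseudo_absences(landscape.reference, 2000, cells, n_sets=1, seed=22)[0]
    radii = {"forest": 7.0, "tem_warmmon": 6.0, "tri": 8.0, "footprint": 1.0}
    Xp, okp = extract_features(landscape, radii, cells)
    Xb, okb = extract_features(landscape, radii, pa.cells)
    Xp, Xb = Xp[okp].reset_index(drop=True), Xb[okb].reset_index(drop=True)
    runs = cross_validate(
        Xp, [Xb], [BaseLearnerSpec(a) for a in ALGORITHMS], k=5, repeats=1, seed=23
    )
    model = build_ensemble(runs, Xp, Xb)
    fitted_map = project_suitability(model, landscape, radii)
    return model, fitted_map, Xp


class TestSyntheticTruthRecovery:
    """The fitted ensemble must track the generating suitability surface."""

    def test_fitted_map_correlates_with_truth(self, fitted, suitability):
        from scipy import stats

        _, fitted_map, _ = fitted
        ok = ~(fitted_map.nodata_mask | suitability.nodata_mask)
        rho = stats.spearmanr(
            fitted_map.values[ok].ravel(), suitability.values[ok].ravel()
        ).statistic
        assert rho > 0.7

    def test_temperature_response_has_interior_maximum(self, fitted):
        model, _, Xp = fitted
        curve = response_curve(model, Xp, "tem_warmmon_r6km", n_points=60)
        peak = int(np.argmax(curve["score"].to_numpy()))
        assert 0 < peak < len(curve) - 1

    def test_projection_is_reproducible(self, fitted, landscape):
        from scalesdm.projection import project_suitability

        model, fitted_map, _ = fitted
        radii = {"forest": 7.0, "tem_warmmon": 6.0, "tri": 8.0, "footprint": 1.0}
        again = project_suitability(model, landscape, radii)
        assert np.array_equal(fitted_map.values, again.values)


def test_cv_metric_dispersion_shrinks_with_sample_size():
    """AUC spread across repeats contracts as the data grows."""
    rng = np.random.default_rng(31)

    def dispersion(n):
        Xp = pd.DataFrame({"a": rng.normal(0.8, 1, n), "b": rng.normal(0, 1, n)})
        Xb = pd.DataFrame({"a": rng.normal(0, 1, 4 * n), "b": rng.normal(0, 1, 4 * n)})
        runs = cross_validate(Xp, [Xb], [BaseLearnerSpec("GLM")], k=3, repeats=4, seed=n)
        return np.std([r.auc for r in runs])

    assert dispersion(2000) < dispersion(50)
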
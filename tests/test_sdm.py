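"""Presence/absence construction, predictor screening, model families,
cross-validated committees and gridded projection."""

import numpy as np
import pandas as pd
import pytest

from trophogeo import sdm
from trophogeo.sdm import (
    EXTENDED_FAMILY_REGISTRY,
    FAMILY_REGISTRY,
    EnsembleSpec,
    FittedModel,
    GLMMember,
    PresenceAbsence,
    SkipMarker,
    THRESHOLD_GRID,
    build_pa,
    cross_validate,
    jaccard_index,
    optimal_threshold,
    optimum_from_profile,
    preliminary_importance,
    project,
    schedule_fits,
    screen_collinearity,
    select_predictors,
)
from conftest import toy_table


def _pa(X: np.ndarray, y: np.ndarray, columns=None) -> PresenceAbsence:
    cols = columns or [f"v{j}" for j in range(X.shape[1])]
    sites = [f"s{i}" for i in range(len(y))]
    return PresenceAbsence(species_id="sp", site_ids=sites, labels=np.asarray(y),
                           predictors=pd.DataFrame(X, index=sites, columns=cols))


class TestBuildPA:
    def _predictors(self, n):
        return pd.DataFrame({"SST": np.linspace(0, 30, n)},
                            index=[f"s{j}" for j in range(n)])

    def test_insufficient_presences_skipped(self):
        counts = np.zeros((1, 100), dtype=int)
        counts[0, :19] = 5
        t = toy_table(counts)
        out = build_pa(t, "sp0", self._predictors(100), min_occurrences=20)
        assert isinstance(out, SkipMarker) and "19" in out.reason

    def test_present_everywhere_is_unmodelable(self):
        t = toy_table(np.full((1, 30), 2))
        out = build_pa(t, "sp0", self._predictors(30), min_occurrences=5)
        assert isinstance(out, SkipMarker) and "absence" in out.reason

    def test_labels_from_counts(self):
        t = toy_table(np.array([[0, 3, 0, 1, 0]]))
        out = build_pa(t, "sp0", self._predictors(5), min_occurrences=1)
        np.testing.assert_array_equal(out.labels, [0, 1, 0, 1, 0])

    def test_unknown_species_rejected(self):
        t = toy_table(np.array([[1, 1]]))
        with pytest.raises(KeyError, match="ghost"):
            build_pa(t, "ghost", self._predictors(2))


class TestJaccard:
    def test_confusion_counts_worked_example(self):
        # TP=3, FP=1, FN=2 -> 3/6
        y_true = np.array([1, 1, 1, 1, 1, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 1, 0])
        assert jaccard_index(y_true, y_pred) == pytest.approx(0.5)

    def test_matches_set_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            sa = {i for i in range(30) if a[i]}
            sb = {i for i in range(30) if b[i]}
            expected = len(sa & sb) / len(sa | sb) if (sa | sb) else 1.0
            assert jaccard_index(a, b) == pytest.approx(expected)

    def test_threshold_search_matches_full_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            p = rng.uniform(size=60)
            thr, j = optimal_threshold(y, p)
            brute = [(jaccard_index(y, p >= t), t) for t in THRESHOLD_GRID]
            best_j = max(b for b, _ in brute)
            best_t = min(t for b, t in brute if b == best_j)
            assert j == pytest.approx(best_j)
            assert thr == pytest.approx(best_t)   # ties toward lower threshold


class TestScreening:
    def test_identical_columns_drop_less_important(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x})
        kept = screen_collinearity(X, {"a": 0.8, "b": 0.2})
        assert kept == ["a"]

    def test_uncorrelated_predictors_all_kept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        kept = screen_collinearity(X, {"a": 1, "b": 2, "c": 3})
        assert kept == ["a", "b", "c"]

    def test_three_mutually_collinear_keep_highest_importance(self):
        x = np.linspace(0, 1, 40)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        kept = screen_collinearity(X, {"a": 3.0, "b": 2.0, "c": 1.0})
        assert kept == ["a"]

    def test_importance_of_pure_noise_is_small(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((1000, 2))
        y = (X[:, 0] > 0).astype(int)
        y = np.where(rng.uniform(size=1000) < 0.05, 1 - y, y)
        imp = preliminary_importance(_pa(X, y, ["signal", "noise"]), seed=0)
        assert imp["noise"] < 0.05
        assert imp["signal"] > imp["noise"]

    def test_constant_column_importance_zero(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.standard_normal(300), np.ones(300)])
        y = (X[:, 0] > 0).astype(int)
        imp = preliminary_importance(_pa(X, y, ["x", "flat"]), seed=0)
        assert imp["flat"] == 0.0

    def test_select_predictors_ranks_true_driver_first(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((600, 4))
        logit = 3.0 * X[:, 2]
        y = (rng.uniform(size=600) < 1 / (1 + np.exp(-logit))).astype(int)
        names = select_predictors(_pa(X, y), top_k=2, seed=0)
        assert names[0] == "v2"


class TestFamilies:
    @pytest.mark.parametrize("family", list(FAMILY_REGISTRY))
    def test_predictions_in_unit_interval_and_deterministic(self, family):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((150, 2))
        y = (X[:, 0] + 0.3 * rng.standard_normal(150) > 0).astype(int)
        a = FAMILY_REGISTRY[family](seed=42).fit(X, y).predict_proba(X)
        b = FAMILY_REGISTRY[family](seed=42).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1

    def test_glm_recovers_logistic_coefficient(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        beta = 1.5
        y = (rng.uniform(size=2000) < 1 / (1 + np.exp(-(0.2 + beta * x)))).astype(int)
        member = GLMMember(seed=0).fit(x[:, None], y)
        assert member.linear_coefficients_[0] == pytest.approx(beta, rel=0.15)

    def test_single_class_training_flagged(self):
        with pytest.raises(sdm.FamilyFitError):
            GLMMember().fit(np.random.default_rng(0).standard_normal((20, 2)),
                            np.ones(20, dtype=int))


class TestCrossValidation:
    def test_schedule_bookkeeping(self):
        sched = schedule_fits([f"sp{i}" for i in range(72)],
                              list(EXTENDED_FAMILY_REGISTRY), 5)
        assert len(sched) == 72 * 5 * 5 == 1800

    def test_separable_data_gives_perfect_glm_member(self):
        x = np.concatenate([np.linspace(-3, -1, 40), np.linspace(1, 3, 40)])
        y = (x > 0).astype(int)
        spec, est = cross_validate(_pa(x[:, None], y), families=("GLM",), n_reps=2, seed=0)
        glm = [m for m in spec.members if m.family == "GLM"]
        assert all(m.jaccard_validation == pytest.approx(1.0) for m in glm)
        assert all(m.retained for m in glm)

    def test_pure_noise_member_rejected_at_low_prevalence(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 2))
        y = (rng.uniform(size=400) < 0.15).astype(int)   # prevalence ~0.15
        spec, est = cross_validate(_pa(X, y), families=("GLM",), n_reps=5, seed=1)
        rejected = [m for m in spec.members if not m.retained]
        assert len(rejected) >= 4   # noise members fail the 0.3 cutoff

    def test_n_trained_is_families_times_reps(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((120, 2))
        y = (X[:, 0] > 0).astype(int)
        spec, est = cross_validate(_pa(X, y), families=("GLM", "MARS"), n_reps=3, seed=0)
        assert spec.n_trained == 6

    def test_empty_stratum_raises_helpful_error(self):
        X = np.random.default_rng(4).standard_normal((30, 2))
        y = np.zeros(30, dtype=int)
        y[0] = 1
        with pytest.raises(ValueError, match="split"):
            cross_validate(_pa(X, y), families=("GLM",))


class _StubModel:
    """Member stub with a fixed per-cell probability field."""

    def __init__(self, value):
        self.value = value

    def predict_proba(self, X):
        v = np.broadcast_to(self.value, (len(X),)).copy()
        return v


def _stub_member(value, threshold=0.5):
    return FittedModel(species_id="sp", family="GLM", cv_rep=0,
                       model=_StubModel(value), calibration_threshold=threshold,
                       jaccard_calibration=1.0, jaccard_validation=1.0,
                       retained=True)


class TestProjection:
    def _ensemble(self, members):
        return EnsembleSpec(species_id="sp", members=members,
                            predictor_names=["SST"], n_trained=len(members))

    def test_split_committee_gives_half(self, env):
        ens = self._ensemble([_stub_member(1.0), _stub_member(0.0)])
        hsi = project(ens, env)
        assert np.all(hsi.monthly == 0.5)

    def test_unanimous_committee_gives_one(self, env):
        ens = self._ensemble([_stub_member(0.9), _stub_member(0.8)])
        assert np.all(project(ens, env).annual == 1.0)

    def test_single_member_map_is_binary(self, env):
        rng = np.random.default_rng(0)

        class Wavy:
            def predict_proba(self, X):
                return 1 / (1 + np.exp(-X[:, 0] / 10))

        m = _stub_member(0.0)
        m.model = Wavy()
        hsi = project(self._ensemble([m]), env)
        assert set(np.unique(hsi.monthly)) <= {0.0, 1.0}

    def test_committee_monotonicity_duplicate_member_is_noop(self, env):
        class Wavy:
            def predict_proba(self, X):
                return 1 / (1 + np.exp(-X[:, 0] / 10))

        a = _stub_member(0.0, threshold=0.6)
        a.model = Wavy()
        b = _stub_member(0.0, threshold=0.6)
        b.model = Wavy()
        one = project(self._ensemble([a]), env)
        two = project(self._ensemble([a, b]), env)
        np.testing.assert_array_equal(one.monthly, two.monthly)

    def test_empty_ensemble_rejected(self, env):
        with pytest.raises(ValueError, match="empty ensemble"):
            project(self._ensemble([]), env)

    def test_missing_predictor_field_named(self, env):
        ens = EnsembleSpec(species_id="sp", members=[_stub_member(1.0)],
                           predictor_names=["KRYPTONITE"], n_trained=1)
        with pytest.raises(KeyError, match="KRYPTONITE"):
            project(ens, env)

    def test_annual_is_mean_of_months(self, env):
        ens = self._ensemble([_stub_member(1.0), _stub_member(0.0)])
        hsi = project(ens, env)
        np.testing.assert_allclose(hsi.annual, hsi.monthly.mean(axis=0))


class TestOptimumFromProfile:
    def test_sharp_peak_recovered_exactly(self):
        env_vals = np.linspace(0, 30, 31)
        profile = np.exp(-((env_vals - 12.0) ** 2))
        assert optimum_from_profile(profile, env_vals) == pytest.approx(12.0)

    def test_plateau_centroid(self):
        env_vals = np.linspace(0, 10, 11)
        profile = np.where((env_vals >= 3) & (env_vals <= 7), 1.0, 0.0)
        assert optimum_from_profile(profile, env_vals) == pytest.approx(5.0)
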
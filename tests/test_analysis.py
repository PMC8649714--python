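import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from mobiphen import analysis, synthetic as syn
from mobiphen.io_gps import SadnessReport
from tests.naive import naive_welch


def rank1_matrix(n=120, seed=0):
    rng = np.random.default_rng(seed)
    profile = rng.uniform(0, 1, 47)
    amp = rng.uniform(1, 10, n)
    return np.outer(amp, profile)


class TestPca:
    def test_rank1_first_component_dominates(self):
        res = analysis.fit_pca(rank1_matrix())
        assert res.explained_var_fraction[0] >= 0.999

    def test_identities(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (100, 47))
        res = analysis.fit_pca(x)
        # orthonormal loadings
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(47), atol=1e-8)
        # explained fractions: non-increasing, in [0,1], summing to 1
        f = res.explained_var_fraction
        assert np.all(np.diff(f) <= 1e-12) and np.all((f >= 0) & (f <= 1))
        assert f.sum() == pytest.approx(1.0, abs=1e-8)
        # reconstruction
        np.testing.assert_allclose(res.scores @ res.loadings.T + res.center, x, atol=1e-8)

    def test_sign_convention_deterministic(self):
        x = rank1_matrix(seed=3)
        r1, r2 = analysis.fit_pca(x), analysis.fit_pca(x.copy())
        np.testing.assert_array_equal(r1.loadings, r2.loadings)
        for k in range(r1.loadings.shape[1]):
            j = np.argmax(np.abs(r1.loadings[:, k]))
            assert r1.loadings[j, k] >= 0

    def test_transform_matches_scores(self):
        x = np.random.default_rng(2).normal(0, 1, (60, 47))
        res = analysis.fit_pca(x)
        np.testing.assert_allclose(res.transform(x), res.scores, atol=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            analysis.fit_pca(np.zeros((40, 47)))


class TestWelch:
    def test_identical_groups(self):
        g = analysis.welch_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert g.t_stat == 0.0 and g.p_value == pytest.approx(1.0)

    def test_hand_computed_case(self):
        """Direct evaluation of the Welch formula for {1..4} vs {11..14}."""
        g = analysis.welch_compare([1, 2, 3, 4], [11, 12, 13, 14], "x")
        t, dof = naive_welch([1.0, 2, 3, 4], [11.0, 12, 13, 14])
        assert g.t_stat == pytest.approx(t, abs=1e-9)
        assert g.t_stat == pytest.approx(-10.9545, abs=1e-4)
        assert g.dof == pytest.approx(dof, abs=1e-9)
        assert g.p_value < 0.001

    def test_matches_naive_on_random_unequal_groups(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            g = analysis.welch_compare(a, b)
            t, dof = naive_welch(list(a), list(b))
            assert g.t_stat == pytest.approx(t, rel=1e-9)
            assert g.dof == pytest.approx(dof, rel=1e-9)

    def test_p_value_consistent_with_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.2, 1.0, 6)
        g = analysis.welch_compare(a, b)
        pooled = np.concatenate([a, b])
        obs = abs(g.t_stat)
        count = total = 0
        for idx in itertools.combinations(range(12), 6):
            mask = np.zeros(12, bool)
            mask[list(idx)] = True
            t_perm = analysis.welch_compare(pooled[mask], pooled[~mask]).t_stat
            count += abs(t_perm) >= obs - 1e-12
            total += 1
        p_perm = count / total
        assert g.p_value == pytest.approx(p_perm, abs=0.05)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 10)
        g1, g2 = analysis.welch_compare(a, b), analysis.welch_compare(b, a)
        assert g1.t_stat == pytest.approx(-g2.t_stat)
        assert g1.p_value == pytest.approx(g2.p_value)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(analysis.DegenerateGroupsError):
            analysis.welch_compare([1.0], [1, 2, 3])
        with pytest.raises(analysis.DegenerateGroupsError):
            analysis.welch_compare([2.0, 2.0], [3.0, 3.0])


class TestAurocHelper:
    def test_random_scorer_near_half_and_monotone_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.random(4000) < 0.5
        ids = np.repeat(np.arange(40), 100)
        scores = rng.normal(0, 1, 4000)
        per = analysis._per_participant_auroc(y, scores, ids)
        assert per.mean() == pytest.approx(0.5, abs=0.03)
        per2 = analysis._per_participant_auroc(y, np.exp(3 * scores), ids)
        pd.testing.assert_series_equal(per, per2)


@pytest.fixture(scope="module")
def coupled_dataset():
    """Prediction dataset from a strongly coupled simulated cohort."""
    regime = dataclasses.replace(syn.PRESETS["pre2020"], n_participants=12, n_days=14)
    coupling = syn.CouplingConfig(betas={"perc_home": 1.5})
    cohort = syn.simulate_cohort(regime, coupling, seed=101)
    X, y, ids, info = analysis.build_prediction_dataset(cohort.traces, cohort.reports)
    return cohort, X, y, ids, info


class TestBuildPredictionDataset:
    def test_min_severe_retention_rule(self, small_cohort):
        # rebuild reports so one participant has exactly 1 severe report
        reports = []
        for pid, n_sev in zip(["P000", "P001", "P002", "P003"], [1, 2, 3, 0]):
            base = [r for r in small_cohort.reports if r.participant_id == pid]
            for k, r in enumerate(base):
                level = "quite_a_bit" if k < n_sev else "not_at_all"
                reports.append(SadnessReport(pid, r.t, level))
        X, y, ids, info = analysis.build_prediction_dataset(small_cohort.traces, reports)
        assert set(ids) == {"P001", "P002"}
        # all reports of retained participants enter, severe or not
        assert (ids == "P001").sum() + (ids == "P002").sum() == len(ids) == 10
        assert info["n_participants_retained"] == 2

    def test_no_retained_participants_signalled(self, small_cohort):
        reports = [SadnessReport(r.participant_id, r.t, "not_at_all") for r in small_cohort.reports]
        with pytest.raises(analysis.DegenerateGroupsError):
            analysis.build_prediction_dataset(small_cohort.traces, reports)

    def test_window_is_half_open(self, coupled_dataset):
        """Features at t_report come from [t−24h, t): a ping exactly at the
        report instant is excluded while one just before is included."""
        from mobiphen import phenotypes as ph
        from tests.conftest import make_trace

        tr = make_trace([0.0, 43200.0, 86400.0], [30.0, 30.0, 31.0], [-97.0] * 3)
        feats = ph.window_features(tr, pd.DataFrame(columns=["t_start", "t_end", "place_id", "lat", "lon"]), None, 0.0, 86400.0)
        # the lat-31 point at exactly t1 is outside the window: no distance
        assert feats["total_dist"] == pytest.approx(0.0, abs=1e-9)

    def test_feature_columns_complete(self, coupled_dataset):
        _, X, y, ids, info = coupled_dataset
        assert list(X.columns) == analysis.PHENOTYPE_NAMES
        assert np.isfinite(X.to_numpy()).all()
        assert len(X) == len(y) == len(ids)


class TestMixedLogistic:
    def test_strong_coupling_recovers_signal(self, coupled_dataset):
        _, X, y, ids, _ = coupled_dataset
        res = analysis.fit_mixed_logistic(X, y, ids)
        assert res.overall_auroc >= 0.65
        assert "conditional_auroc" in res.extras

    def test_null_coupling_marginal_auroc_near_half(self):
        """Labels independent of mobility: population-level AUROC ≈ 0.5.

        Uses the generator's planted (noise-free) window features directly so
        several seeds stay cheap; labels are pure Bernoulli noise (no feature
        weight, no random intercept), so anything above 0.5 is in-sample
        optimism, which at 500 rows and 6 features stays small.
        """
        regime = dataclasses.replace(syn.PRESETS["pre2020"], n_participants=25, n_days=20)
        feats = [f"win_{k}" for k in syn.COUPLABLE_FEATURES]
        vals = []
        for seed in range(10):
            cohort = syn.simulate_cohort(regime, syn.CouplingConfig(betas={}, sigma_u=0.0), seed=300 + seed)
            X = cohort.truth[feats].rename(columns=lambda c: c[4:])
            y = cohort.truth["severe"].to_numpy()
            if len(np.unique(y)) < 2:
                continue
            res = analysis.fit_mixed_logistic(X, y, cohort.truth["participant_id"].to_numpy())
            vals.append(res.overall_auroc)
        assert 0.45 <= np.mean(vals) <= 0.58

    def test_one_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(analysis.DegenerateGroupsError):
            analysis.fit_mixed_logistic(X, np.ones(10), np.repeat(["p", "q"], 5))


class TestRfLoocv:
    def test_deterministic_given_seed(self, coupled_dataset):
        _, X, y, ids, _ = coupled_dataset
        r1 = analysis.rf_loocv_auroc(X, y, ids, seed=4, n_estimators=50)
        r2 = analysis.rf_loocv_auroc(X, y, ids, seed=4, n_estimators=50)
        pd.testing.assert_series_equal(r1.per_unit_auroc, r2.per_unit_auroc)

    def test_strong_coupling_beats_chance(self, coupled_dataset):
        _, X, y, ids, _ = coupled_dataset
        res = analysis.rf_loocv_auroc(X, y, ids, seed=0, n_estimators=200)
        assert res.mean_auroc >= 0.6
        assert 0.0 <= res.per_unit_auroc.min() and res.per_unit_auroc.max() <= 1.0

    def test_too_few_participants_rejected(self):
        X = pd.DataFrame({"a": np.arange(8.0)})
        y = np.tile([0, 1], 4).astype(bool)
        with pytest.raises(analysis.DegenerateGroupsError):
            analysis.rf_loocv_auroc(X, y, np.repeat(["p", "q"], 4), seed=0)


@pytest.fixture(scope="module")
def two_cohort_features():
    pre = dataclasses.replace(syn.PRESETS["pre2020"], n_participants=6, n_days=6)
    mid = dataclasses.replace(syn.PRESETS["mid2020"], n_participants=6, n_days=6)
    ca = syn.simulate_cohort(pre, seed=31)
    cb = syn.simulate_cohort(mid, seed=32)
    fa = analysis.extract_cohort_features(ca.traces)
    fb = analysis.extract_cohort_features(cb.traces)
    return fa, fb


class TestCompareGroups:
    def test_full_battery_shape(self, two_cohort_features):
        fa, fb = two_cohort_features
        tab = analysis.compare_groups(fa, fb)
        assert len(tab) == 22
        assert set(tab["metric_name"]) >= {"PC1", "PC10", "IS", "RA", "num_pls", "routine_idx"}
        assert tab["p_value"].between(0, 1).all()
        assert tab["p_adjusted"].between(0, 1).all()
        assert (tab["p_adjusted"] >= tab["p_value"] - 1e-12).all()

    def test_swapping_groups_negates_t(self, two_cohort_features):
        fa, fb = two_cohort_features
        t1 = analysis.compare_groups(fa, fb)
        t2 = analysis.compare_groups(fb, fa)
        np.testing.assert_allclose(t1["t_stat"], -t2["t_stat"], atol=1e-9)

    def test_pooled_pca_mean_score_identity(self, two_cohort_features):
        """Group mean score difference equals the projection of the group
        mean-DDP difference onto the loading (linearity of pooled PCA)."""
        fa, fb = two_cohort_features
        dcols = [f"d{i+1:02d}" for i in range(47)]
        pooled = pd.concat([fa.ddp, fb.ddp], ignore_index=True)
        pca = analysis.fit_pca(pooled[dcols].to_numpy())
        sa = pca.transform(fa.ddp[dcols].to_numpy())
        sb = pca.transform(fb.ddp[dcols].to_numpy())
        mean_diff = fa.ddp[dcols].mean().to_numpy() - fb.ddp[dcols].mean().to_numpy()
        np.testing.assert_allclose(
            sa.mean(axis=0) - sb.mean(axis=0), mean_diff @ pca.loadings, atol=1e-8
        )

    def test_day_level_unit_available(self, two_cohort_features):
        fa, fb = two_cohort_features
        tab = analysis.compare_groups(fa, fb, unit="day")
        n_days_a = len(fa.ddp)
        assert tab.loc[tab["metric_name"] == "PC1", "n_a"].iloc[0] == n_days_a
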
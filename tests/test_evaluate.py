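"""Cross-validated scores, the robustness battery and component selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spocflow import evaluate, spoc
from spocflow.evaluate import (
    ComponentEvaluation,
    CvScheme,
    SelectionThresholds,
    classify_predictor,
)

from conftest import make_scene


def make_eval(**kw):
    n = kw.pop("n_epochs", 400)
    defaults = dict(
        z_true=np.zeros(n),
        z_est=np.zeros(n),
        rank=0,
        fold_correlations=np.full(5, 0.2),
        fold_patterns=[],
        r_all=0.3,
        r_folds=0.3,
        h_folds=5,
        z_auc=0.65,
        aauc_snr=0.3,
        n_epochs=n,
    )
    defaults.update(kw)
    return ComponentEvaluation(**defaults)


class TestCvScheme:
    def test_fold_sizes_balanced_contiguous(self):
        folds = CvScheme(5).folds(403)
        assert [len(f) for f in folds] == [81, 81, 81, 80, 80]
        flat = np.concatenate(folds)
        assert np.array_equal(flat, np.arange(403))  # contiguous, ordered

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            CvScheme(5).folds(9)


class TestCorrelations:
    def test_r_all_extremes(self):
        z = np.random.default_rng(0).standard_normal(50)
        assert evaluate.r_all(z, z) == pytest.approx(1.0)
        assert evaluate.r_all(z, -z) == pytest.approx(-1.0)

    def test_r_all_constant_flagged_nan(self):
        z = np.random.default_rng(0).standard_normal(50)
        assert np.isnan(evaluate.r_all(z, np.ones(50)))

    def test_r_folds_equals_r_all_for_single_fold(self):
        rng = np.random.default_rng(1)
        z, y = rng.standard_normal(50), rng.standard_normal(50)
        assert evaluate.r_folds(z, y, CvScheme(1)) == pytest.approx(evaluate.r_all(z, y))

    def test_r_folds_ignores_pure_across_fold_trend(self):
        """Predictions sharing only a fold-level trend with the truth score
        high on R_all but near zero on R_folds — the session-trend
        signature."""
        rng = np.random.default_rng(2)
        scheme = CvScheme(5)
        n = 400
        fold_level = np.repeat(np.arange(5, dtype=float), 80)
        z_true = 3.0 * fold_level + rng.standard_normal(n)
        z_est = 3.0 * fold_level + rng.standard_normal(n)
        assert evaluate.r_all(z_true, z_est) > 0.8
        assert abs(evaluate.r_folds(z_true, z_est, scheme)) < 0.15


class TestHFolds:
    @pytest.mark.parametrize(
        "r_all, fold_r, expected",
        [
            (0.4, [0.2, 0.1, 0.3, 0.05, 0.15], 5),
            (0.4, [0.2, -0.1, 0.3, 0.05, 0.15], 4),
            (0.4, [0.2, 0.0, 0.3, 0.05, 0.15], 5),   # zero counts as a match
            (-0.4, [-0.2, -0.1, 0.3, -0.05, -0.15], 4),
        ],
    )
    def test_sign_homogeneity(self, r_all, fold_r, expected):
        assert evaluate.h_folds(r_all, np.array(fold_r)) == expected


class TestZAuc:
    def test_perfect_and_inverted_ranking(self):
        z = np.random.default_rng(3).standard_normal(100)
        assert evaluate.z_auc(z, z) == 1.0
        assert evaluate.z_auc(z, -z) == 0.0

    def test_independent_scores_near_chance(self):
        rng = np.random.default_rng(4)
        aucs = [
            evaluate.z_auc(rng.standard_normal(400), rng.standard_normal(400))
            for _ in range(50)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_degenerate_single_class_flagged(self):
        assert np.isnan(evaluate.z_auc(np.ones(10), np.arange(10)))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transforms(self, seed):
        """z-AUC is a rank statistic: strictly increasing transforms of the
        prediction scores leave it unchanged."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(60)
        y = rng.standard_normal(60)
        base = evaluate.z_auc(z, y)
        assert evaluate.z_auc(z, np.exp(y)) == pytest.approx(base)
        assert evaluate.z_auc(z, y**3) == pytest.approx(base)


class TestCrossval:
    def test_planted_scene_recovered(self, small_covs):
        covs, z, _ = small_covs
        ev = evaluate.crossval_predict(None, z, covs=covs)
        assert ev.valid
        assert ev.r_all >= 0.6
        assert np.all(np.isfinite(ev.z_est))

    def test_deterministic(self, small_covs):
        covs, z, _ = small_covs
        e1 = evaluate.crossval_predict(None, z, covs=covs)
        e2 = evaluate.crossval_predict(None, z, covs=covs)
        assert np.array_equal(e1.z_est, e2.z_est)

    def test_shuffled_target_yields_null_correlations(self, small_covs):
        """Permuted labels break the power-target link; R_all falls inside
        the null band 2/sqrt(N) for most permutations."""
        covs, z, _ = small_covs
        rng = np.random.default_rng(10)
        inside = 0
        n_rep = 25
        for _ in range(n_rep):
            zp = rng.permutation(z)
            ev = evaluate.crossval_predict(None, zp, covs=covs)
            inside += abs(ev.r_all) <= 2 / np.sqrt(len(z))
        assert inside >= 0.7 * n_rep

    def test_invalid_rank_raises(self, small_covs):
        covs, z, _ = small_covs
        with pytest.raises(ValueError, match="rank"):
            evaluate.crossval_predict(None, z, rank=99, covs=covs)


class TestAaucSnr:
    def test_area_normalization(self):
        assert evaluate._area_over_chance(np.full(7, 0.5)) == pytest.approx(0.0)
        assert evaluate._area_over_chance(np.full(7, 1.0)) == pytest.approx(0.5)

    def test_deterministic_given_seed(self, small_covs):
        covs, z, _ = small_covs
        a1 = evaluate.aauc_snr(None, z, covs=covs, seed=5)
        a2 = evaluate.aauc_snr(None, z, covs=covs, seed=5)
        assert a1 == a2

    def test_monotone_in_planted_effect(self):
        """Stronger planted comodulation survives more label noise."""
        diffs = []
        for seed in range(3):
            _, z_hi, _ = (eph, zh, _) = make_scene(seed=30 + seed, r=0.9)
            covs_hi = spoc.epoch_covariances(eph)
            epl, z_lo, _ = make_scene(seed=60 + seed, r=0.2)
            covs_lo = spoc.epoch_covariances(epl)
            hi = evaluate.aauc_snr(None, zh, covs=covs_hi, seed=seed)
            lo = evaluate.aauc_snr(None, z_lo, covs=covs_lo, seed=seed)
            diffs.append(hi - lo)
        assert np.mean(diffs) > 0


class TestSelection:
    def test_default_thresholds_pass(self):
        assert evaluate.passes_selection(make_eval())

    @pytest.mark.parametrize(
        "kw",
        [
            dict(z_auc=0.58),          # below separability threshold 0.59
            dict(h_folds=4),           # one fold flipped sign
            dict(aauc_snr=0.17),       # below stability threshold 0.18
            dict(aauc_snr=None),       # stress test not run
            dict(n_epochs=149),        # below convergence minimum
            dict(valid=False),
        ],
    )
    def test_each_criterion_excludes(self, kw):
        assert not evaluate.passes_selection(make_eval(**kw))

    def test_select_components_filters_list(self):
        evs = [make_eval(), make_eval(z_auc=0.5), make_eval(h_folds=3)]
        assert evaluate.select_components(evs) == [evs[0]]

    def test_custom_thresholds(self):
        th = SelectionThresholds(z_auc_min=0.9, aauc_min=0.0, h_folds_min=5, n_e_min=10)
        assert not evaluate.passes_selection(make_eval(), th)


class TestClassifyPredictor:
    def test_trend_free_scene_is_single_trial(self):
        epochs, z, _ = make_scene(seed=40)
        ev = evaluate.crossval_predict(epochs, z)
        assert classify_predictor(ev) == "single_trial"

    def test_trend_coupled_scene_is_session_trend(self):
        from spocflow import synthgen

        scene = synthgen.SyntheticScene(
            n_channels=8, n_epochs=200, sampling_rate=200.0, epoch_length=0.75,
            trend_weight=0.6,
            sources=[synthgen.SourceSpec(comodulation_r=0.95, coupling="trend")],
            noise_power=0.1, seed=41,
        )
        epochs, z, _ = synthgen.generate_scene(scene)
        ev = evaluate.crossval_predict(epochs, z)
        assert ev.r_all > 0.2
        assert abs(ev.r_folds) < 0.5 * abs(ev.r_all)
        assert classify_predictor(ev) == "session_trend"

    def test_null_scene_is_neither(self):
        epochs, z, _ = make_scene(seed=42, r=0.0)
        ev = evaluate.crossval_predict(epochs, z)
        assert classify_predictor(ev) == "neither"
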
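"""Prefilter, Boruta, base/meta training, ROC metrics, and the stacked
classifier's contracts."""

import numpy as np
import pandas as pd
import pytest

from cfmesa.mesa import (
    BorutaSelector,
    MannWhitneyPrefilter,
    MesaClassifier,
    MesaConfig,
    NonNegativeLogisticCombiner,
    biomarker_cv,
    cross_cohort_apply,
    roc_metrics,
    run_loocv,
    train_base,
    train_meta,
)
from cfmesa.simulate import generate_multimodal_dataset

LIGHT = MesaConfig(boruta_max_iter=10, rf_estimators=20)


def _noise_frame(rng, n=20, p=30, prefix="f"):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(p)],
    )


def _labels(n):
    return np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]


class TestPrefilter:
    def test_perfect_separator_ranked_first(self, rng):
        X = _noise_frame(rng, 20, 50)
        y = _labels(20)
        X["f7"] = np.where(y == 1, 5.0, -5.0) + rng.normal(0, 0.1, 20)
        pre = MannWhitneyPrefilter(k=10).fit(X, y)
        assert pre.selected_ids_[0] == "f7"

    def test_k_above_available_keeps_all(self, rng, caplog):
        X = _noise_frame(rng, 10, 3)
        pre = MannWhitneyPrefilter(k=5).fit(X, _labels(10))
        assert len(pre.selected_ids_) == 3

    def test_ranking_matches_per_feature_mwu(self, rng):
        from scipy import stats

        X = _noise_frame(rng, 16, 200)
        y = _labels(16)
        pre = MannWhitneyPrefilter(k=200).fit(X, y)
        expected = {
            c: stats.mannwhitneyu(
                X[c][y == 1], X[c][y == 0], alternative="two-sided"
            ).pvalue
            for c in X.columns
        }
        got = pre.pvalues_
        assert max(abs(got[c] - expected[c]) for c in X.columns) < 1e-12
        ranked_p = [got[c] for c in pre.selected_ids_]
        assert ranked_p == sorted(ranked_p)

    def test_heavily_missing_feature_dropped_and_rest_imputed(self, rng):
        X = _noise_frame(rng, 20, 5)
        X.iloc[:10, 0] = np.nan  # 50% missing -> dropped
        X.iloc[0, 1] = np.nan    # 5% missing -> imputed
        pre = MannWhitneyPrefilter(k=5).fit(X, _labels(20))
        assert "f0" not in pre.selected_ids_
        out = pre.transform(X)
        assert not out.isna().any().any()


class TestBoruta:
    def test_planted_features_recovered(self, rng):
        recovered = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = _noise_frame(r, 40, 100)
            y = _labels(40)
            for j in range(5):
                X[f"f{j}"] = np.where(y == 1, 1.5, -1.5) + r.normal(0, 1, 40)
            sel = BorutaSelector(
                k_target=5, max_iter=20, n_estimators=40, random_state=seed
            ).fit(X, y)
            recovered += set(sel.selected_ids_) == {f"f{j}" for j in range(5)}
        assert recovered >= 9

    def test_permuted_labels_confirm_nothing(self, rng):
        empty = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = _noise_frame(r, 30, 40)
            y = r.permutation(_labels(30))
            sel = BorutaSelector(
                k_target=10, max_iter=15, n_estimators=25, random_state=seed
            ).fit(X, y)
            empty += len(sel.confirmed_) == 0
            assert len(sel.selected_ids_) == 10  # backfill reaches k_target
        assert empty >= 9

    def test_same_seed_identical_selection(self, rng):
        X = _noise_frame(rng, 24, 50)
        y = _labels(24)
        a = BorutaSelector(k_target=8, max_iter=10, random_state=3).fit(X, y)
        b = BorutaSelector(k_target=8, max_iter=10, random_state=3).fit(X, y)
        assert a.selected_ids_ == b.selected_ids_

    def test_shortcut_when_features_at_most_k_target(self, rng):
        X = _noise_frame(rng, 10, 6)
        sel = BorutaSelector(k_target=10).fit(X, _labels(10))
        assert sel.selected_ids_ == list(X.columns)
        assert sel.n_iter_ == 0


class TestBaseAndMeta:
    def test_separable_toy_reaches_training_auc_one(self, rng):
        X = pd.DataFrame({"a": np.r_[np.ones(5), np.zeros(5)],
                          "b": rng.normal(size=10)})
        y = _labels(10)
        est = train_base(X, y, seed=0)
        auc, _, _ = roc_metrics(est.predict_proba(X.to_numpy())[:, 1], y)
        assert auc == 1.0

    def test_label_permutation_gives_null_cv_auc(self, rng):
        from sklearn.model_selection import StratifiedKFold

        X = _noise_frame(rng, 40, 20)
        y = rng.permutation(_labels(40))
        probs = np.zeros(40)
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y):
            est = train_base(X.iloc[tr], y[tr], seed=0)
            probs[te] = est.predict_proba(X.iloc[te].to_numpy())[:, 1]
        auc, _, _ = roc_metrics(probs, y)
        assert 0.2 <= auc <= 0.8

    def test_prediction_contract(self, rng):
        X = _noise_frame(rng, 12, 4)
        est = train_base(X, _labels(12), seed=1)
        p = est.predict_proba(X.to_numpy())[:, 1]
        assert p.shape == (12,)
        assert ((0 <= p) & (p <= 1)).all()

    def test_single_class_rejected(self, rng):
        X = _noise_frame(rng, 6, 3)
        with pytest.raises(ValueError, match="both classes"):
            train_base(X, np.ones(6, int), seed=0)

    def test_identical_perfect_columns_give_auc_one(self, rng):
        y = _labels(30)
        col = y + rng.normal(0, 0.01, 30)
        oof = np.column_stack([col] * 4)
        meta = train_meta(oof, y, seed=0)
        auc, _, _ = roc_metrics(meta.predict_proba(oof)[:, 1], y)
        assert auc == 1.0

    def test_stacking_no_harm_with_one_informative_column(self, rng):
        y = _labels(40)
        info = 0.8 * y + rng.normal(0, 0.3, 40)
        cols = np.column_stack([info] + [rng.random(40) for _ in range(3)])
        cols = 1 / (1 + np.exp(-cols))
        meta = train_meta(cols, y, seed=0)
        combined_auc, _, _ = roc_metrics(meta.predict_proba(cols)[:, 1], y)
        info_auc, _, _ = roc_metrics(cols[:, 0], y)
        assert combined_auc >= info_auc - 0.05

    def test_combiner_monotone_in_each_input(self, rng):
        y = _labels(30)
        oof = rng.random((30, 4))
        meta = NonNegativeLogisticCombiner().fit(oof, y)
        grid = np.linspace(0, 1, 11)
        base = np.full(4, 0.5)
        for j in range(4):
            points = np.tile(base, (11, 1))
            points[:, j] = grid
            out = meta.predict_proba(points)[:, 1]
            assert (np.diff(out) >= -1e-12).all()

    def test_constant_columns_tolerated(self):
        y = _labels(20)
        oof = np.full((20, 4), 0.5)
        meta = train_meta(oof, y, seed=0)
        assert np.isfinite(meta.predict_proba(oof)[:, 1]).all()


class TestRocMetrics:
    def test_perfect_separation(self):
        auc, roc, sens0 = roc_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and sens0 == 1.0

    def test_all_tied_scores(self):
        auc, _, sens0 = roc_metrics([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5 and sens0 == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.random(200)
        scores[::5] = scores[1::5][:40]  # inject ties
        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 1, 0
        auc, _, _ = roc_metrics(scores, y)
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_metrics([0.1, 0.2], [1, 1])


class TestMesaClassifier:
    def _signal_data(self, seed=0, n_a=10, n_b=10):
        return generate_multimodal_dataset(
            n_per_group={"sALS": n_a, "control": n_b},
            n_features={"cgi_meth": 30, "dhs_meth": 30, "occupancy": 25, "wps": 20},
            n_informative={"cgi_meth": 8, "dhs_meth": 8, "occupancy": 5, "wps": 5},
            delta_beta=0.2, shift_sd=1.5, seed=seed, scheme_seed=1000 + seed,
        )

    def test_marker_counts_never_exceed_targets(self):
        mats, labels, _ = self._signal_data()
        model = MesaClassifier(config=LIGHT, random_state=0).fit(mats, labels)
        for modality, markers in model.markers_.items():
            assert len(markers) <= LIGHT.boruta_k[modality]

    def test_resubstitution_equals_identity_cohort_application(self):
        mats, labels, _ = self._signal_data()
        model = MesaClassifier(config=LIGHT, random_state=0).fit(mats, labels)
        direct = model.predict_proba(mats)[:, 1]
        report = cross_cohort_apply(model, mats, labels)
        auc, _, _ = roc_metrics(direct, labels.isin(["sALS"]).astype(int))
        assert report.auc == pytest.approx(auc)

    def test_generalizes_to_cohort_from_same_process(self):
        mats_a, labels_a, _ = self._signal_data(seed=0)
        model = MesaClassifier(config=LIGHT, random_state=0).fit(mats_a, labels_a)
        mats_b, labels_b, _ = generate_multimodal_dataset(
            n_per_group={"sALS": 10, "control": 8},
            n_features={"cgi_meth": 30, "dhs_meth": 30, "occupancy": 25, "wps": 20},
            n_informative={"cgi_meth": 8, "dhs_meth": 8, "occupancy": 5, "wps": 5},
            delta_beta=0.2, shift_sd=1.5, seed=77, scheme_seed=1000,
        )
        report = cross_cohort_apply(model, mats_b, labels_b)
        assert report.auc >= 0.8

    def test_permuted_cohort_b_labels_give_null_auc(self, rng):
        mats, labels, _ = self._signal_data()
        model = MesaClassifier(config=LIGHT, random_state=0).fit(mats, labels)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        report = cross_cohort_apply(model, mats, permuted)
        assert 0.2 <= report.auc <= 0.8

    def test_mostly_absent_markers_rejected(self):
        mats, labels, _ = self._signal_data()
        model = MesaClassifier(config=LIGHT, random_state=0).fit(mats, labels)
        crippled = {
            m: fm.values.iloc[:, :2] for m, fm in mats.items()
        }
        with pytest.raises(ValueError, match="absent"):
            model.predict_proba(crippled)

    def test_loocv_gives_one_outoffold_prediction_per_sample(self):
        mats, labels, _ = self._signal_data(n_a=6, n_b=6)
        report = run_loocv(mats, labels, config=LIGHT, seed=0, compute_ci=False)
        assert len(report.probabilities) == 12
        assert list(report.probabilities.index) == list(labels.index)
        assert ((report.probabilities >= 0) & (report.probabilities <= 1)).all()

    def test_loocv_recovers_planted_signal(self):
        mats, labels, _ = self._signal_data(n_a=10, n_b=10)
        report = run_loocv(mats, labels, config=LIGHT, seed=0, compute_ci=False)
        assert report.auc >= 0.85


def test_biomarker_cv_hand_example_and_scale_invariance(rng):
    cols = pd.MultiIndex.from_tuples([("chr1", 1), ("chr1", 2)])
    beta = pd.DataFrame(
        [[0.2, 0.7], [0.4, 0.7], [0.6, 0.7]],
        index=["a", "b", "c"], columns=cols,
    )
    groups = pd.Series(["sALS", "sALS", "sALS"], index=["a", "b", "c"])
    table = biomarker_cv(beta, list(cols), groups)
    assert table["sALS"].iloc[0] == pytest.approx(0.5)  # sd 0.2 / mean 0.4
    assert table["sALS"].iloc[1] == pytest.approx(0.0, abs=1e-12)
    scaled = biomarker_cv(beta * 0.5, list(cols), groups)
    assert scaled["sALS"].iloc[0] == pytest.approx(0.5)
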
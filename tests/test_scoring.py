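import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import igensigrx as ig
from igensigrx.features import parse_feature_id
from igensigrx.scoring import (
    DLine,
    IGenSigModel,
    class_score,
    fit_dline,
    predict,
    signed_distance,
    train,
)
from igensigrx.weighting import SENSITIVE


class TestClassScore:
    def test_single_feature_identity(self):
        assert class_score([0.5], [1.0]) == (0.5, 1)

    def test_plain_mean_when_no_redundancy(self):
        score, n = class_score([0.2, 0.6], [1.0, 1.0])
        assert score == pytest.approx(0.4, abs=1e-12)
        assert n == 2

    def test_duplicated_feature_pair(self):
        # (2 * 0.5/sqrt(2)) / (2/sqrt(2)) = 0.5
        score, _ = class_score([0.5, 0.5], [2.0, 2.0])
        assert score == pytest.approx(0.5, abs=1e-12)

    def test_empty_present_set_scores_zero_with_flag(self):
        assert class_score([], []) == (0.0, 0)

    def test_bounded_by_omega_range(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            w = rng.uniform(0.13, 1.0, n)
            eps = rng.uniform(1.0, 5.0, n)
            score, _ = class_score(w, eps)
            assert w.min() - 1e-12 <= score <= w.max() + 1e-12

    def test_rejects_eps_below_one(self):
        with pytest.raises(ValueError):
            class_score([0.5], [0.5])


def _scan_best_J(sens, res, y, n=10_000):
    ang = np.arctan2(sens, res)
    nonzero = (np.asarray(sens) != 0) | (np.asarray(res) != 0)
    best = -2.0
    for theta in np.linspace(0.0, math.pi / 2, n):
        pred = nonzero & (ang > theta)
        pos = y == 1
        J = pred[pos].mean() + (~pred[~pos]).mean() - 1
        best = max(best, J)
    return best


class TestDLine:
    def test_separable_clouds_hit_J_of_one(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.repeat([1, 0], n // 2)
        ang = np.where(y == 1, rng.uniform(1.0, 1.5, n), rng.uniform(0.1, 0.6, n))
        r = rng.uniform(0.2, 1.0, n)
        sens, res = r * np.sin(ang), r * np.cos(ang)
        d = fit_dline(sens, res, y)
        pred = signed_distance(sens, res, d) > 0
        assert (pred == (y == 1)).all()  # J = 1
        # chosen angle sits inside the separating gap
        assert 0.6 < d.angle < 1.0

    def test_degenerate_identical_points_fall_back_to_slope_one(self, caplog):
        y = np.array([1, 0, 1, 0])
        with caplog.at_level("WARNING"):
            d = fit_dline([0.3, 0.3, 0.3, 0.3], [0.2, 0.2, 0.2, 0.2], y)
        assert d.fallback and d.slope == pytest.approx(1.0)

    def test_hand_points_match_exhaustive_scan(self):
        sens = np.array([0.9, 0.8, 0.3, 0.55, 0.2, 0.1])
        res = np.array([0.2, 0.5, 0.4, 0.5, 0.7, 0.8])
        y = np.array([1, 1, 1, 0, 0, 0])
        d = fit_dline(sens, res, y)
        pred = signed_distance(sens, res, d) > 0
        pos = y == 1
        J_fit = pred[pos].mean() + (~pred[~pos]).mean() - 1
        assert J_fit >= _scan_best_J(sens, res, y) - 1e-12

    def test_fitted_J_beats_scanned_slopes_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            sens = rng.uniform(0, 1, n)
            res = rng.uniform(0, 1, n)
            d = fit_dline(sens, res, y)
            pred = signed_distance(sens, res, d) > 0
            pos = y == 1
            J_fit = pred[pos].mean() + (~pred[~pos]).mean() - 1
            assert J_fit >= _scan_best_J(sens, res, y, n=2000) - 1e-12

    def test_requires_both_labels(self):
        with pytest.raises(ValueError):
            fit_dline([0.1, 0.2], [0.2, 0.1], [1, 1])


class TestSignedDistance:
    def test_point_on_line_scores_zero(self):
        d = DLine(slope=2.0, angle=math.atan(2.0))
        assert signed_distance(2.0, 1.0, d) == pytest.approx(0.0, abs=1e-12)

    def test_slope_one_unit_points(self):
        d = DLine(slope=1.0, angle=math.atan(1.0))
        assert signed_distance(1.0, 0.0, d) == pytest.approx(1 / math.sqrt(2))
        assert signed_distance(0.0, 1.0, d) == pytest.approx(-1 / math.sqrt(2))


class TestTrain:
    def test_selected_sensitive_features_enriched_for_planted_genes(
        self, small_cohort, small_features, small_corpus, small_model
    ):
        from igensigrx.features import drop_weak_level_features

        cfg, expr, muts, y, truth = small_cohort
        wt = small_model.weight_table()
        selected = wt.index[wt["class"] == SENSITIVE]
        planted = set(truth.sensitive_genes)
        universe = drop_weak_level_features(small_features).index
        n_planted = sum(parse_feature_id(f).gene in planted for f in universe)
        hits = sum(parse_feature_id(f).gene in planted for f in selected)
        # hypergeometric enrichment of planted-gene features among selected
        p = hypergeom.sf(hits - 1, len(universe), n_planted, len(selected))
        fold = (hits / len(selected)) / (n_planted / len(universe))
        assert fold >= 2.0
        assert p < 1e-6

    def test_permuted_labels_select_near_null_fraction(self):
        # at the trial-scale cohort size (n = 200) the chance rate of
        # phi >= 0.13 stays below 5% of features per class
        from igensigrx.weighting import phi_profile

        cfg = ig.GeneratorConfig(seed=23, n_genes=100, n_sensitive_genes=8, n_resistant_genes=8)
        expr, muts, y, _ = ig.generate_cohort(cfg)
        fm = ig.cohort_feature_matrix(expr, muts)
        rng = np.random.default_rng(17)
        fractions = []
        for _ in range(20):
            yp = rng.permutation(y.to_numpy())
            phi = phi_profile(fm.to_numpy(), yp)
            # per-class selected fraction at the default cutoff
            fractions.append(np.nansum(phi >= 0.13) / len(fm))
        assert np.mean(fractions) <= 0.05

    def test_training_prediction_is_reproducible(self, small_features, small_model):
        a = predict(small_model, small_features)
        b = predict(small_model, small_features)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.contributions, b.contributions)

    def test_train_is_deterministic(self, small_cohort, small_features, small_corpus):
        cfg, expr, muts, y, truth = small_cohort
        m1 = train(small_features, y, small_corpus)
        m2 = train(small_features, y, small_corpus)
        assert json.dumps(m1.to_dict(), sort_keys=True) == json.dumps(
            m2.to_dict(), sort_keys=True
        )

    def test_error_when_no_feature_passes(self, small_features, small_corpus, small_cohort):
        *_, y, _ = small_cohort
        with pytest.raises(ValueError, match="no predictive features"):
            train(
                small_features,
                y,
                small_corpus,
                ig.TrainConfig(cutoff=0.9999),
            )


class TestPredict:
    def test_identical_presence_gives_identical_scores(self, small_features, small_model):
        fm = small_features
        clone = fm.copy()
        clone.columns = [f"copy_{s}" for s in fm.columns]
        st_orig = predict(small_model, fm)
        st_clone = predict(small_model, clone)
        np.testing.assert_allclose(
            st_orig.scores[["sensitive_score", "resistant_score"]].to_numpy(),
            st_clone.scores[["sensitive_score", "resistant_score"]].to_numpy(),
        )

    def test_sample_without_selected_features_is_flagged(self, small_features, small_model):
        fm = small_features.copy()
        fm["blank"] = 0
        st = predict(small_model, fm)
        row = st.scores.loc["blank"]
        assert row["uninformative"] == 1
        assert row["final_score"] == pytest.approx(0.0)
        assert row["predicted_label"] == 0

    def test_zero_overlap_is_an_error(self, small_model):
        fm = pd.DataFrame(
            np.ones((2, 3), dtype=np.uint8),
            index=["ZZZ_Up_Level5", "YYY_Mut"],
            columns=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="overlap"):
            predict(small_model, fm)

    def test_contributions_reconstruct_scores(self, small_features, small_model):
        st = predict(small_model, small_features)
        contrib = st.contributions
        sample = small_features.columns[0]
        sub = contrib[(contrib["sample_id"] == sample) & (contrib["class"] == SENSITIVE)]
        if len(sub):
            inv = 1.0 / np.sqrt(sub["epsilon"].to_numpy())
            expected = np.sum(sub["omega"].to_numpy() * inv) / np.sum(inv)
            assert st.scores.loc[sample, "sensitive_score"] == pytest.approx(expected)

    def test_adding_strong_isolated_feature_raises_score(self):
        # a feature with omega above the current class score, alone in its
        # cluster (eps = 1), strictly raises the weighted mean
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(1, 8))
            w = rng.uniform(0.13, 0.8, n)
            eps = rng.uniform(1.0, 4.0, n)
            before, _ = class_score(w, eps)
            w_new = before + rng.uniform(0.01, 0.2)
            after, _ = class_score(np.append(w, w_new), np.append(eps, 1.0))
            assert after > before


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path, small_features, small_model):
        p = tmp_path / "model.json"
        small_model.save(p)
        loaded = IGenSigModel.load(p)
        p2 = tmp_path / "model2.json"
        loaded.save(p2)
        assert p.read_bytes() == p2.read_bytes()
        a = predict(small_model, small_features)
        b = predict(loaded, small_features)
        assert (
            a.scores.to_csv(sep="\t") == b.scores.to_csv(sep="\t")
        )  # bit-identical prediction

    def test_corrupted_model_rejected(self, tmp_path, small_model):
        p = tmp_path / "model.json"
        small_model.save(p)
        d = json.loads(p.read_text())
        d["format_version"] = 99
        p.write_text(json.dumps(d))
        with pytest.raises(ValueError):
            IGenSigModel.load(p)
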
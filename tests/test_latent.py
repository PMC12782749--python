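"""Normalization, SVD eigenfeature space, and effect-size ranking."""

import numpy as np
import pandas as pd
import pytest

from epinet.features import FeatureMatrix, n_sliding_windows
from epinet.latent import (
    fit_eigenspace,
    normalize_feature_matrix,
    normalize_within_subject,
    project,
    rank_by_effect_size,
    within_subject_validation,
)


class TestNormalizeWithinSubject:
    def test_three_point_example(self):
        assert np.allclose(normalize_within_subject(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_max_maps_to_one(self, rng):
        x = rng.standard_normal(31)
        out = normalize_within_subject(x)
        assert abs(out.max() - 1.0) < 1e-12
        assert abs(np.median(out)) < 1e-12

    def test_constant_vector_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize_within_subject(np.full(5, 2.0))
        assert np.allclose(out, 0.0)


class TestEigenspace:
    def test_identity_input_signed_permutation(self):
        U = fit_eigenspace(np.eye(5))
        assert np.allclose(np.abs(U) @ np.abs(U).T, np.eye(5), atol=1e-12)
        assert np.allclose(np.abs(U).sum(axis=0), 1.0)

    def test_orthonormal_and_lossless(self, rng):
        X = rng.standard_normal((6, 20))
        U = fit_eigenspace(X)
        assert np.allclose(U.T @ U, np.eye(6), atol=1e-8)
        Phi = project(U, X)
        assert abs(np.linalg.norm(Phi) - np.linalg.norm(X)) < 1e-8
        assert np.allclose(U @ Phi, X, atol=1e-8)

    def test_sign_convention_reproducible_under_column_order(self, rng):
        X = rng.standard_normal((5, 30))
        perm = rng.permutation(30)
        U1 = fit_eigenspace(X)
        U2 = fit_eigenspace(X[:, perm])
        assert np.allclose(np.abs(U1), np.abs(U2), atol=1e-8)

    def test_nan_rejected_with_row_names(self, rng):
        X = rng.standard_normal((4, 10))
        X[2, 3] = np.nan
        with pytest.raises(ValueError, match="2"):
            fit_eigenspace(X)

    def test_identity_projection(self, rng):
        X = rng.standard_normal((4, 9))
        assert np.allclose(project(np.eye(4), X), X)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            project(np.eye(4), rng.standard_normal((5, 9)))


class TestEffectSizeRanking:
    def test_hand_computed_cohens_d(self):
        Phi = np.array([[0.0, 2.0, 4.0, 6.0]])
        pos = np.array([False, False, True, True])
        res = rank_by_effect_size(Phi, pos, n_shuffles=50, seed=0, r=1)
        assert abs(res["d"][0] - 4 / np.sqrt(2)) < 1e-12

    def test_null_groups_inside_bounds(self, rng):
        Phi = rng.standard_normal((10, 120))
        pos = np.arange(120) < 40
        res = rank_by_effect_size(Phi, pos, n_shuffles=500, seed=1)
        inside = (res["d"] >= res["lower"]) & (res["d"] <= res["upper"])
        assert inside.sum() >= 8  # ~95% of 10 under the null

    def test_planted_coefficient_ranks_first(self, rng):
        for trial in range(5):
            Phi = rng.standard_normal((12, 100))
            pos = np.arange(100) < 30
            Phi[7, pos] += 2.5
            res = rank_by_effect_size(Phi, pos, n_shuffles=100, seed=trial)
            assert res["ranking"][0] == 7

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_by_effect_size(rng.standard_normal((3, 10)), np.zeros(10, bool))


class TestWithinSubjectValidation:
    def test_identical_subjects_give_common_d(self, rng):
        block = rng.standard_normal((4, 20))
        pos_block = np.arange(20) < 8
        block[1, pos_block] += 2.0
        Phi = np.hstack([block] * 3)
        pos = np.hstack([pos_block] * 3)
        subjects = np.repeat(["a", "b", "c"], 20)
        med = within_subject_validation(Phi, pos, subjects)
        from epinet.spikes import cohens_d

        expected = cohens_d(block[1, pos_block], block[1, ~pos_block])
        assert abs(med[1] - expected) < 1e-12

    def test_median_robust_to_outlier_subject(self, rng):
        blocks, poss, subs = [], [], []
        for i in range(5):
            b = rng.standard_normal((3, 20))
            p = np.arange(20) < 10
            b[0, p] += 20.0 if i == 4 else 1.0  # one wild outlier subject
            blocks.append(b)
            poss.append(p)
            subs.append(np.full(20, f"s{i}"))
        med = within_subject_validation(
            np.hstack(blocks), np.hstack(poss), np.concatenate(subs)
        )
        assert med[0] < 5.0

    def test_single_label_subject_excluded_with_warning(self, rng):
        Phi = rng.standard_normal((2, 30))
        pos = np.array([True] * 5 + [False] * 5 + [True] * 10 + [True] * 5 + [False] * 5)
        subjects = np.repeat(["a", "b", "c"], 10)
        with pytest.warns(UserWarning, match="b"):
            within_subject_validation(Phi, pos, subjects)


class TestNormalizeFeatureMatrix:
    def _fm(self, X, subjects):
        rows = pd.DataFrame({"feature": ["f"] * X.shape[0], "frequency": range(X.shape[0])})
        cols = pd.DataFrame(
            {
                "subject_id": subjects,
                "channel_id": [f"c{i}" for i in range(X.shape[1])],
                "label": ["nonEpiNet"] * X.shape[1],
            }
        )
        return FeatureMatrix(X=X, rows=rows, cols=cols)

    def test_per_subject_median_and_max(self):
        X = np.array([[1.0, 2.0, 3.0, 10.0, 20.0, 30.0]])
        fm = self._fm(X, ["a"] * 3 + ["b"] * 3)
        out = normalize_feature_matrix(fm)
        assert np.allclose(out.X, [[-1, 0, 1, -1, 0, 1]])

    def test_nan_imputed_to_subject_median(self):
        X = np.array([[1.0, np.nan, 3.0, 5.0]])
        fm = self._fm(X, ["a"] * 4)
        with pytest.warns(UserWarning, match="imputed"):
            out = normalize_feature_matrix(fm)
        assert np.all(np.isfinite(out.X))


class TestSlidingWindowCount:
    def test_seven_hour_recording(self):
        # 7 h with a 10 min window and 1 min step -> (420 - 10)/1 + 1
        assert n_sliding_windows(7 * 3600.0, 600.0, 60.0) == 411

    def test_exact_window_gives_one(self):
        assert n_sliding_windows(600.0, 600.0, 60.0) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            n_sliding_windows(500.0, 600.0, 60.0)


class TestDimensionalContract:
    def test_default_configuration_has_260_rows(self):
        from epinet.config import PipelineConfig
        from epinet.features import feature_row_table

        cfg = PipelineConfig.default()
        assert cfg.n_features == 260
        table = feature_row_table(cfg)
        assert len(table) == 260
        assert (table["feature"] == "dfa").sum() == 20
        assert (table["feature"] == "evc").sum() == 50

    def test_reduced_preset_row_contract(self, trained, cfg):
        _, info = trained
        assert info["features"].k == cfg.n_features

    def test_rank1_eigenfeature_loads_on_discriminative_features(self, trained):
        """The leading retained eigenfeature loads on the raw features that
        actually separate the planted groups."""
        model, info = trained
        fm = info["features_norm"]
        pos = info["positive"]
        from epinet.spikes import cohens_d

        d_raw = np.array(
            [cohens_d(row[pos], row[~pos]) for row in fm.X]
        )
        loading = np.abs(model.latent.U_reduced[0])
        top_load = np.argsort(-loading)[:10]
        # at least half of the top-10 loadings sit on raw features that
        # themselves separate the planted groups strongly
        assert np.mean(np.abs(d_raw[top_load]) >= 1.0) >= 0.5
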
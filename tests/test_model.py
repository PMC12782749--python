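"""Consensus membership, saliency surface, AUC, supervised baseline."""

import numpy as np
import pytest

from epinet.model import (
    EpiNetModel,
    build_saliency_surface,
    correlate_membership_spikes,
    evaluate_auc,
    fit_memberships,
    fuzzy_c_means,
    global_saliency,
    lookup_saliency,
    supervised_baseline,
)


def _two_blobs(rng, n=60, sep=6.0, dims=4):
    a = rng.standard_normal((n, dims))
    b = rng.standard_normal((n, dims))
    a[:, 0] += sep
    return np.vstack([a, b]).T  # (r, q) with Phi1 = first row


class TestFuzzyCMeans:
    def test_separated_blobs_assigned_to_their_cluster(self, rng):
        X = _two_blobs(rng).T
        u, centers = fuzzy_c_means(X, n_clusters=2, seed=0)
        hi_cluster = int(np.argmax(centers[:, 0]))
        assert u[:60, hi_cluster].mean() > 0.75  # shifted blob
        assert u[60:, hi_cluster].mean() < 0.25
        assert abs(centers[hi_cluster, 0] - 6.0) < 1.0


class TestFitMemberships:
    def test_two_blobs_near_binary_consensus(self, rng):
        Phi = _two_blobs(rng)
        res = fit_memberships(Phi, component_counts=range(2, 5), seed=0)
        m = res["consensus"]
        assert np.all((m >= 0) & (m <= 1))
        assert m[:60].mean() > 0.9  # high-Phi1 blob
        assert m[60:].mean() < 0.1

    def test_single_blob_centered_memberships(self, rng):
        Phi = rng.standard_normal((4, 120))
        res = fit_memberships(Phi, component_counts=range(2, 5), seed=0)
        m = res["consensus"]
        assert 0.25 < m.mean() < 0.75
        # no crisp bimodality: few channels at the extremes
        assert np.mean((m < 0.02) | (m > 0.98)) < 0.5

    def test_classifiers_agree_on_planted_cohort(self, trained):
        _, info = trained
        memb = info["memberships"]
        r = np.corrcoef(memb["gmm_mean"], memb["fcm_mean"])[0, 1]
        assert r > 0.8

    def test_channel_order_invariance(self, rng):
        Phi = _two_blobs(rng, n=40)
        perm = rng.permutation(Phi.shape[1])
        m1 = fit_memberships(Phi, range(2, 4), seed=0)["consensus"]
        m2 = fit_memberships(Phi[:, perm], range(2, 4), seed=0)["consensus"]
        assert np.allclose(m1[perm], m2, atol=0.05)

    def test_common_affine_rescaling_invariance(self, rng):
        """Scaling and shifting all retained coefficients consistently
        leaves the consensus membership unchanged."""
        Phi = _two_blobs(rng, n=40)
        m1 = fit_memberships(Phi, range(2, 4), seed=0)["consensus"]
        m2 = fit_memberships(2.5 * Phi + 3.0, range(2, 4), seed=0)["consensus"]
        assert np.allclose(m1, m2, atol=0.05)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fit_memberships(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestSaliencySurface:
    def test_bin_mean_recovered_at_center(self, rng):
        phi1 = rng.uniform(0, 1, 500)
        phi2 = rng.uniform(0, 1, 500)
        m = np.where(phi1 > 0.5, 0.7, 0.2)
        surf = build_saliency_surface(phi1, phi2, m, n_bins=5)
        xc = 0.5 * (surf.x_edges[:-1] + surf.x_edges[1:])
        yc = 0.5 * (surf.y_edges[:-1] + surf.y_edges[1:])
        i, j = 4, 2
        assert np.isfinite(surf.bin_means[i, j])
        val = lookup_saliency(surf, xc[i], yc[j])
        assert abs(val - surf.bin_means[i, j]) < 1e-6

    def test_linear_ramp_interpolates_midway(self, rng):
        phi1 = rng.uniform(0, 1, 2000)
        phi2 = rng.uniform(0, 1, 2000)
        m = phi1  # linear ramp along Phi1
        surf = build_saliency_surface(phi1, phi2, m, n_bins=10)
        xc = 0.5 * (surf.x_edges[:-1] + surf.x_edges[1:])
        yc = 0.5 * (surf.y_edges[:-1] + surf.y_edges[1:])
        mid = 0.5 * (xc[3] + xc[4])
        val = lookup_saliency(surf, mid, yc[5])
        expected = 0.5 * (surf.bin_means[3, 5] + surf.bin_means[4, 5])
        assert abs(val - expected) < 0.02

    def test_far_queries_clipped(self, rng):
        phi1, phi2 = rng.uniform(0, 1, 300), rng.uniform(0, 1, 300)
        surf = build_saliency_surface(phi1, phi2, rng.uniform(0, 1, 300))
        vals = lookup_saliency(surf, np.array([-100.0, 100.0]), np.array([-100.0, 100.0]))
        assert np.all((vals >= 0) & (vals <= 1))

    def test_bounds_hold_for_many_random_queries(self, rng):
        phi1, phi2 = rng.standard_normal(400), rng.standard_normal(400)
        surf = build_saliency_surface(phi1, phi2, rng.uniform(0, 1, 400))
        q1 = rng.uniform(-10, 10, 100_000)
        q2 = rng.uniform(-10, 10, 100_000)
        vals = lookup_saliency(surf, q1, q2)
        assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_nonfinite_queries_yield_nan(self, rng):
        phi1, phi2 = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        surf = build_saliency_surface(phi1, phi2, rng.uniform(0, 1, 200))
        vals = lookup_saliency(surf, np.array([np.nan, 0.5]), np.array([0.5, 0.5]))
        assert np.isnan(vals[0]) and np.isfinite(vals[1])

    def test_constant_coefficients_constant_over_time(self, rng):
        phi1, phi2 = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        surf = build_saliency_surface(phi1, phi2, rng.uniform(0, 1, 200))
        lam = lookup_saliency(surf, np.full(10, 0.4), np.full(10, 0.6))
        assert np.ptp(lam) < 1e-12

    def test_training_channels_self_consistent(self, trained):
        model, info = trained
        Phi = info["Phi_reduced"]
        lam = model.assess(Phi)
        # mean absolute deviation from binned membership surface
        assert np.nanmean(np.abs(lam - model.membership)) < 0.05

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            build_saliency_surface(np.array([0.5]), np.array([0.5]), np.array([1.0]))


class TestGlobalSaliency:
    def test_identical_channels(self):
        lam = np.tile(np.linspace(0, 1, 7), (5, 1))
        assert np.allclose(global_saliency(lam), np.linspace(0, 1, 7))

    def test_nan_channels_excluded(self):
        lam = np.array([[0.2, 0.4], [np.nan, 0.8]])
        assert np.allclose(global_saliency(lam), [0.2, 0.6])

    def test_all_nan_time_point_warns(self):
        lam = np.array([[np.nan, 0.5], [np.nan, 0.7]])
        with pytest.warns(UserWarning):
            out = global_saliency(lam)
        assert np.isnan(out[0]) and abs(out[1] - 0.6) < 1e-12


class TestAUC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        pos = np.array([True, True, False, False])
        assert evaluate_auc(scores, pos) == 1.0

    def test_reversal_antisymmetry(self, rng):
        scores = rng.standard_normal(50)
        pos = rng.random(50) < 0.4
        a = evaluate_auc(scores, pos)
        assert abs(evaluate_auc(-scores, pos) - (1.0 - a)) < 1e-12

    def test_random_labels_near_half(self, rng):
        aucs = [
            evaluate_auc(rng.standard_normal(200), rng.random(200) < 0.5)
            for _ in range(50)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_nan(self):
        assert np.isnan(evaluate_auc(np.array([1.0, 2.0]), np.array([True, True])))


class TestSupervisedBaseline:
    def _cohort(self, rng, shift):
        feats, pos, subs = [], [], []
        for s in range(6):
            x = rng.standard_normal((20, 12))
            p = np.arange(20) < 5
            x[p, :4] += shift
            feats.append(x)
            pos.append(p)
            subs.append(np.full(20, f"s{s}"))
        return np.vstack(feats), np.concatenate(pos), np.concatenate(subs)

    def test_planted_contrast_high_auc(self, rng):
        feats, pos, subs = self._cohort(rng, 3.0)
        df = supervised_baseline(feats, pos, subs, seed=0)
        assert df["auc_rf"].mean() > 0.9
        assert df["auc_xgb"].mean() > 0.9

    def test_null_cohort_chance_auc(self, rng):
        feats, pos, subs = self._cohort(rng, 0.0)
        df = supervised_baseline(feats, pos, subs, seed=0)
        assert abs(df[["auc_rf", "auc_xgb"]].to_numpy().mean() - 0.5) < 0.15

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            supervised_baseline(
                rng.standard_normal((10, 3)),
                np.arange(10) < 5,
                np.repeat(["a", "b"], 5),
            )


class TestMembershipSpikeCorrelation:
    def test_perfect_monotone_relation(self, rng):
        phi1 = rng.uniform(0, 1, 600)
        phi2 = rng.uniform(0, 1, 600)
        m = phi1 + phi2
        res = correlate_membership_spikes(phi1, phi2, m, 2.0 * m + 1.0,
                                          n_bins=8, n_permutations=100, seed=0)
        assert res["rho"] > 0.999

    def test_independent_inside_null(self, rng):
        phi1 = rng.uniform(0, 1, 600)
        phi2 = rng.uniform(0, 1, 600)
        res = correlate_membership_spikes(
            phi1, phi2, rng.random(600), rng.random(600),
            n_bins=8, n_permutations=200, seed=1,
        )
        assert res["p"] > 0.01

    def test_too_few_pixels_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate_membership_spikes(
                np.full(20, 0.5), np.full(20, 0.5), rng.random(20), rng.random(20)
            )


class TestModelSerialization:
    def test_round_trip_preserves_assessment(self, trained, tmp_path):
        model, info = trained
        path = tmp_path / "model.epinet"
        model.save(path)
        loaded = EpiNetModel.load(path)
        Phi = info["Phi_reduced"]
        assert np.allclose(model.assess(Phi), loaded.assess(Phi), equal_nan=True)
        assert np.allclose(model.latent.U_reduced, loaded.latent.U_reduced)

    def test_unknown_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.npz"
        np.savez(bad, header="{}", junk=np.zeros(3))
        with pytest.raises((ValueError, KeyError)):
            EpiNetModel.load(bad)
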
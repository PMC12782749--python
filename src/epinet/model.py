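"""Consensus EpiNet membership and the (Phi1, Phi2) saliency surface.

Channels pooled across training subjects are soft-clustered in the
retained eigenfeature coordinates with two classifiers resting on
different assumptions — Gaussian mixture models and Fuzzy C-means — each
fit with 2 clusters on the top-n coefficients for n = 2..10. Memberships
are averaged across n within each classifier and the two classifier means
are averaged into the consensus membership M_hat in [0, 1] (values near 1:
likely EpiNet). Clusters are oriented so the cluster with the higher mean
Phi1 is "EpiNet"; when labels are available at training time the
orientation is checked for positive-class enrichment.

The saliency surface bins the training (Phi1, Phi2) plane into 30 x 30
linear bins, takes the per-bin mean M_hat, and fits a lookup surface:
piecewise-linear interpolation between populated bin centres inside the
data support, nearest-value extension outside, clipped to [0, 1]. Applied
to sliding-window coefficients of a new recording it yields the
time-resolved saliency lambda_hat(q, t); its channel average Lambda_hat(t)
is the momentary global EpiNet-saliency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.stats import rankdata, spearmanr
from sklearn.mixture import GaussianMixture

from .latent import LatentSpace


# ---------------------------------------------------------------------------
# soft clustering


def fuzzy_c_means(
    X: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy C-means soft clustering.

    Returns (memberships (n, c), centers (c, d)). Memberships follow the
    standard inverse-distance update with fuzzifier ``m``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(n_clusters), size=n)
    centers = np.zeros((n_clusters, X.shape[1]))
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return u, centers


def fit_memberships(
    Phi: np.ndarray,
    component_counts: range | list[int] = range(2, 11),
    seed: int = 0,
    positive: np.ndarray | None = None,
) -> dict:
    """Consensus soft-clustering EpiNet membership from retained coefficients.

    Parameters
    ----------
    Phi : (r, q) retained coefficients, rank-1 first
    component_counts : input-dimension counts; for each n the classifiers
        are fit with 2 clusters on the top-n coefficients
    positive : optional training labels; used only to warn if the
        Phi1-based cluster orientation is not positive-class enriched

    Returns dict with ``consensus``, ``gmm_mean``, ``fcm_mean`` and the raw
    per-count memberships.
    """
    Phi = np.asarray(Phi, dtype=float)
    if not np.all(np.isfinite(Phi)):
        raise ValueError("retained coefficients must be finite")
    r, q = Phi.shape
    if q < 2:
        raise ValueError("need at least 2 channels")
    counts = [n for n in component_counts if n <= r]
    if not counts:
        raise ValueError("no usable component count <= retained rank")
    phi1 = Phi[0]
    gmm_runs, fcm_runs = [], []
    for n in counts:
        X = Phi[:n].T  # (q, n)
        gmm_runs.append(_gmm_membership(X, phi1, seed))
        u, centers = fuzzy_c_means(X, n_clusters=2, m=2.0, seed=seed)
        fcm_runs.append(_orient(u, phi1))
    gmm_mean = np.mean(gmm_runs, axis=0)
    fcm_mean = np.mean(fcm_runs, axis=0)
    consensus = 0.5 * (gmm_mean + fcm_mean)
    if positive is not None:
        pos = np.asarray(positive, dtype=bool)
        if consensus[pos].mean() < consensus[~pos].mean():
            warnings.warn(
                "Phi1-oriented EpiNet cluster is not positive-class enriched"
            )
    return {
        "consensus": consensus,
        "gmm_mean": gmm_mean,
        "fcm_mean": fcm_mean,
        "gmm_runs": np.asarray(gmm_runs),
        "fcm_runs": np.asarray(fcm_runs),
        "component_counts": counts,
    }


def _gmm_membership(X: np.ndarray, phi1: np.ndarray, seed: int) -> np.ndarray:
    last_err = None
    for attempt in range(6):
        try:
            gm = GaussianMixture(
                n_components=2, covariance_type="full",
                random_state=seed + attempt, n_init=2, reg_covar=1e-6,
            )
            gm.fit(X)
            return _orient(gm.predict_proba(X), phi1)
        except Exception as exc:  # pragma: no cover - rare numeric failure
            last_err = exc
    raise RuntimeError(f"GMM failed to converge after retries: {last_err}")


def _orient(u: np.ndarray, phi1: np.ndarray) -> np.ndarray:
    """Column of u belonging to the higher-mean-Phi1 cluster = EpiNet."""
    mean0 = np.average(phi1, weights=np.maximum(u[:, 0], 1e-12))
    mean1 = np.average(phi1, weights=np.maximum(u[:, 1], 1e-12))
    return u[:, 1] if mean1 >= mean0 else u[:, 0]


# ---------------------------------------------------------------------------
# saliency surface


@dataclass
class SaliencySurface:
    """30 x 30 binned consensus-membership map over (Phi1, Phi2) + lookup."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_means: np.ndarray  # (nx, ny), NaN for empty bins
    _linear: LinearNDInterpolator = None
    _nearest: NearestNDInterpolator = None

    def lookup(self, phi1: np.ndarray, phi2: np.ndarray) -> np.ndarray:
        """Saliency lambda_hat in [0, 1]; NaN for non-finite queries."""
        phi1 = np.asarray(phi1, dtype=float)
        phi2 = np.asarray(phi2, dtype=float)
        out = np.full(np.broadcast(phi1, phi2).shape, np.nan)
        ok = np.isfinite(phi1) & np.isfinite(phi2)
        pts = np.column_stack(
            [np.broadcast_to(phi1, out.shape)[ok], np.broadcast_to(phi2, out.shape)[ok]]
        )
        vals = self._linear(pts)
        miss = ~np.isfinite(vals)
        if miss.any():
            vals[miss] = self._nearest(pts[miss])
        out[ok] = np.clip(vals, 0.0, 1.0)
        return out


def build_saliency_surface(
    phi1: np.ndarray,
    phi2: np.ndarray,
    membership: np.ndarray,
    n_bins: int = 30,
) -> SaliencySurface:
    """Bin the training (Phi1, Phi2) plane and fit the lookup surface."""
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    membership = np.asarray(membership, dtype=float)
    x_edges = np.linspace(phi1.min(), phi1.max(), n_bins + 1)
    y_edges = np.linspace(phi2.min(), phi2.max(), n_bins + 1)
    sums, _, _ = np.histogram2d(phi1, phi2, bins=[x_edges, y_edges], weights=membership)
    counts, _, _ = np.histogram2d(phi1, phi2, bins=[x_edges, y_edges])
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    populated = np.nonzero(counts > 0)
    if populated[0].size < 2:
        raise ValueError("need at least 2 populated bins to fit a surface")
    pts = np.column_stack([xc[populated[0]], yc[populated[1]]])
    vals = means[populated]
    nearest = NearestNDInterpolator(pts, vals)
    if populated[0].size >= 3 and np.linalg.matrix_rank(pts - pts.mean(0)) == 2:
        linear = LinearNDInterpolator(pts, vals)
    else:  # degenerate (collinear) support: nearest only
        linear = NearestNDInterpolator(pts, vals)
    return SaliencySurface(
        x_edges=x_edges, y_edges=y_edges, bin_means=means,
        _linear=linear, _nearest=nearest,
    )


def lookup_saliency(
    surface: SaliencySurface, phi1: np.ndarray, phi2: np.ndarray
) -> np.ndarray:
    """Vectorized lambda_hat lookup over channels (x time)."""
    return surface.lookup(phi1, phi2)


def global_saliency(lam: np.ndarray) -> np.ndarray:
    """Lambda_hat(t): channel mean of lambda_hat, NaN channels excluded."""
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(lam, axis=0)
    if np.any(~np.isfinite(out)):
        warnings.warn("all-NaN time points in global saliency")
    return out


# ---------------------------------------------------------------------------
# evaluation


def evaluate_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of scores for the positive class.

    Midranks handle ties; returns NaN if either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    ok = np.isfinite(scores)
    scores, positive = scores[ok], positive[ok]
    n1 = int(positive.sum())
    n0 = positive.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_over_time(lam: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """AUC(t) of per-channel saliency against labels, per time point."""
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    return np.array([evaluate_auc(lam[:, t], positive) for t in range(lam.shape[1])])


def supervised_baseline(
    features: np.ndarray,
    positive: np.ndarray,
    subjects: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out AUC of two tree-ensemble classifiers.

    ``features`` is (n_channels, n_features) band-collapsed input; rows of
    the returned frame give per-held-out-subject AUCs for a bagged forest
    (``rf``) and a gradient-boosted ensemble (``xgb``). Held-out subjects
    with a single class are skipped with a warning.
    """
    from sklearn.ensemble import RandomForestClassifier
    from xgboost import XGBClassifier

    features = np.asarray(features, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    subjects = np.asarray(subjects)
    uniq = pd.unique(subjects)
    if uniq.size < 3:
        raise ValueError("need >= 3 subjects for leave-one-subject-out")
    features = np.nan_to_num(features, nan=0.0)
    rows = []
    for sub in uniq:
        test = subjects == sub
        if positive[test].sum() == 0 or (~positive[test]).sum() == 0:
            warnings.warn(f"held-out subject {sub} single-class; skipped")
            continue
        rf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        xgb = XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.3,
            random_state=seed, n_jobs=1, verbosity=0,
        )
        rf.fit(features[~test], positive[~test])
        xgb.fit(features[~test], positive[~test].astype(int))
        rows.append(
            {
                "subject_id": sub,
                "auc_rf": evaluate_auc(
                    rf.predict_proba(features[test])[:, 1], positive[test]
                ),
                "auc_xgb": evaluate_auc(
                    xgb.predict_proba(features[test])[:, 1], positive[test]
                ),
            }
        )
    return pd.DataFrame(rows)


def correlate_membership_spikes(
    phi1: np.ndarray,
    phi2: np.ndarray,
    membership: np.ndarray,
    spike_densities: np.ndarray,
    n_bins: int = 30,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Rank correlation between binned mean membership and spike density.

    Both quantities are averaged over the same (Phi1, Phi2) bins; the
    correlation is computed across populated (nonzero-count) pixels with a
    permutation p-value.
    """
    phi1 = np.asarray(phi1, float)
    phi2 = np.asarray(phi2, float)
    x_edges = np.linspace(phi1.min(), phi1.max(), n_bins + 1)
    y_edges = np.linspace(phi2.min(), phi2.max(), n_bins + 1)
    counts, _, _ = np.histogram2d(phi1, phi2, bins=[x_edges, y_edges])
    m_sum, _, _ = np.histogram2d(
        phi1, phi2, bins=[x_edges, y_edges], weights=np.asarray(membership, float)
    )
    s_sum, _, _ = np.histogram2d(
        phi1, phi2, bins=[x_edges, y_edges], weights=np.asarray(spike_densities, float)
    )
    mask = counts > 0
    if mask.sum() < 10:
        raise ValueError("fewer than 10 nonzero pixels; cannot correlate")
    m_pix = (m_sum[mask] / counts[mask]).ravel()
    s_pix = (s_sum[mask] / counts[mask]).ravel()
    rho = spearmanr(m_pix, s_pix).statistic
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            spearmanr(m_pix, rng.permutation(s_pix)).statistic
            for _ in range(n_permutations)
        ]
    )
    p = (np.sum(np.abs(null) >= abs(rho)) + 1) / (n_permutations + 1)
    return {"rho": float(rho), "p": float(p), "n_pixels": int(mask.sum())}


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class EpiNetModel:
    """Portable bundle: latent space + saliency surface + provenance."""

    latent: LatentSpace
    surface: SaliencySurface
    membership: np.ndarray  # training consensus M_hat
    config_hash: str = ""
    seed: int = 0

    def assess(self, Phi_rqt: np.ndarray) -> np.ndarray:
        """lambda_hat for (r, q[, t]) retained coefficients."""
        Phi = np.asarray(Phi_rqt, dtype=float)
        return self.surface.lookup(Phi[0], Phi[1])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "format": "epinet-model",
            "version": 1,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "feature_rows": self.latent.feature_rows.to_dict("list")
            if self.latent.feature_rows is not None
            else None,
        }
        with open(path, "wb") as fh:
            np.savez(
                fh,
                header=json.dumps(header),
                U=self.latent.U,
                ranking=self.latent.ranking,
                effect_sizes=self.latent.effect_sizes,
                surrogate_lower=self.latent.surrogate_lower,
                surrogate_upper=self.latent.surrogate_upper,
                ranked_upper=self.latent.ranked_upper,
                max_null_95=self.latent.max_null_95,
                retained=self.latent.retained,
                U_reduced=self.latent.U_reduced,
                membership=self.membership,
                x_edges=self.surface.x_edges,
                y_edges=self.surface.y_edges,
                bin_means=self.surface.bin_means,
            )

    @classmethod
    def load(cls, path: str | Path) -> "EpiNetModel":
        with np.load(Path(path), allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            if header.get("format") != "epinet-model":
                raise ValueError(f"{path}: not an epinet model file")
            rows = header.get("feature_rows")
            latent = LatentSpace(
                U=z["U"],
                ranking=z["ranking"],
                effect_sizes=z["effect_sizes"],
                surrogate_lower=z["surrogate_lower"],
                surrogate_upper=z["surrogate_upper"],
                ranked_upper=z["ranked_upper"],
                max_null_95=float(z["max_null_95"]),
                retained=z["retained"],
                U_reduced=z["U_reduced"],
                feature_rows=pd.DataFrame(rows) if rows else None,
            )
            means = z["bin_means"]
            xc = 0.5 * (z["x_edges"][:-1] + z["x_edges"][1:])
            yc = 0.5 * (z["y_edges"][:-1] + z["y_edges"][1:])
            populated = np.nonzero(np.isfinite(means))
            pts = np.column_stack([xc[populated[0]], yc[populated[1]]])
            vals = means[populated]
            nearest = NearestNDInterpolator(pts, vals)
            if pts.shape[0] >= 3 and np.linalg.matrix_rank(pts - pts.mean(0)) == 2:
                linear = LinearNDInterpolator(pts, vals)
            else:
                linear = nearest
            surface = SaliencySurface(
                x_edges=z["x_edges"], y_edges=z["y_edges"], bin_means=means,
                _linear=linear, _nearest=nearest,
            )
            return cls(
                latent=latent,
                surface=surface,
                membership=z["membership"],
                config_hash=header.get("config_hash", ""),
                seed=int(header.get("seed", 0)),
            )
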
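"""Canonical polyadic (CP) decomposition and cross-domain validation.

The time-resolved sleep feature tensor X (k features x q contacts x t
windows) is factorized into R rank-1 components, each an outer product of
a contact vector theta, a feature vector chi, and a time vector tau.
Fitting is alternating least squares with several random restarts; the
relative reconstruction error is non-increasing over iterations and the
best restart is kept.

Validation analyses: Spearman correlation of each component's time loading
against the global saliency and the global spike density (significance by
circular-shift surrogates, which preserve autocorrelation); inter-contact
similarity matrices from component loadings, saliency time courses and
spike-density time courses; Mantel-style cross-matrix correlations; and
label contrasts on the contact loadings of the saliency-linked component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr, ttest_ind

from .spikes import cohens_d


@dataclass
class TCModel:
    """CP factors and fit diagnostics."""

    theta: np.ndarray  # (q, R) contact vectors
    chi: np.ndarray  # (k, R) feature vectors
    tau: np.ndarray  # (t, R) time vectors
    weights: np.ndarray  # (R,) component norms
    fit_error: float  # final relative reconstruction error
    error_history: np.ndarray = field(default=None)
    converged: bool = True
    seed: int = 0

    @property
    def rank(self) -> int:
        return self.theta.shape[1]

    def reconstruct(self) -> np.ndarray:
        return np.einsum(
            "r,kr,qr,tr->kqt", self.weights, self.chi, self.theta, self.tau
        )


def _unfold(T: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def _normalize_factors(factors: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    weights = np.ones(factors[0].shape[1])
    out = []
    for f in factors:
        norms = np.linalg.norm(f, axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        weights = weights * norms
        out.append(f / norms)
    return out, weights


def cp_decompose(
    X: np.ndarray,
    R: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
    n_restarts: int = 3,
    standardize: bool = True,
) -> TCModel:
    """CP decomposition of a (k, q, t) tensor by alternating least squares.

    NaNs must be imputed beforehand. When ``standardize`` is set, each
    feature slice is z-scored over (contacts x time) before fitting so
    heterogeneous feature scales do not dominate; loadings then describe
    relative modulation. Best of ``n_restarts`` random initializations is
    returned; relative error is checked to be non-increasing per iteration.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected a 3-way tensor (k, q, t)")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains NaN/inf; impute per feature first")
    if standardize:
        mu = X.mean(axis=(1, 2), keepdims=True)
        sd = X.std(axis=(1, 2), keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise ValueError("zero tensor")
    ss = np.random.SeedSequence(seed)
    best: TCModel | None = None
    for restart_ss in ss.spawn(n_restarts):
        rng = np.random.default_rng(restart_ss)
        model = _cp_als_single(X, R, rng, max_iter, tol, norm_x)
        if best is None or model.fit_error < best.fit_error:
            best = model
    best.seed = seed
    return best


def _cp_als_single(X, R, rng, max_iter, tol, norm_x) -> TCModel:
    dims = X.shape  # (k, q, t)
    factors = [rng.standard_normal((d, R)) for d in dims]
    unfolds = [_unfold(X, m) for m in range(3)]
    grams = [f.T @ f for f in factors]
    errors = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        for mode in range(3):
            others = [m for m in range(3) if m != mode]
            kr = _khatri_rao(factors[others[0]], factors[others[1]])
            gram = grams[others[0]] * grams[others[1]]
            sol = np.linalg.lstsq(gram.T, (unfolds[mode] @ kr).T, rcond=None)[0].T
            factors[mode] = sol
            grams[mode] = sol.T @ sol
        err = np.linalg.norm(X - _reconstruct(factors)) / norm_x
        errors.append(err)
        if prev - err < tol:
            converged = True
            break
        prev = err
    if not converged:
        warnings.warn("CP-ALS did not converge within max_iter; returning best fit")
    nf, weights = _normalize_factors(factors)
    order = np.argsort(weights)[::-1]
    return TCModel(
        theta=nf[1][:, order],
        chi=nf[0][:, order],
        tau=nf[2][:, order],
        weights=weights[order],
        fit_error=float(errors[-1]),
        error_history=np.asarray(errors),
        converged=converged,
    )


def _reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    return np.einsum("kr,qr,tr->kqt", *factors)


def factor_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """|cosine| similarity between two factor vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


def match_components(
    model: TCModel, theta0: np.ndarray, chi0: np.ndarray, tau0: np.ndarray
) -> np.ndarray:
    """Greedy matching of estimated to planted components.

    Returns the minimum (over matched pairs) of the product of the three
    per-mode congruences — the standard congruence score per component.
    """
    R0 = theta0.shape[1]
    scores = np.zeros((model.rank, R0))
    for i in range(model.rank):
        for j in range(R0):
            scores[i, j] = (
                factor_congruence(model.theta[:, i], theta0[:, j])
                * factor_congruence(model.chi[:, i], chi0[:, j])
                * factor_congruence(model.tau[:, i], tau0[:, j])
            )
    matched = np.zeros(R0)
    used = set()
    for j in np.argsort(-scores.max(axis=0)):
        order = np.argsort(-scores[:, j])
        for i in order:
            if i not in used:
                used.add(i)
                matched[j] = scores[i, j]
                break
    return matched


def correlate_time_loadings(
    tau: np.ndarray,
    reference: np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-component Spearman rho of time loadings against a reference.

    Significance bounds come from circular-shift surrogates of the
    reference, preserving its autocorrelation.
    """
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    if tau.shape[0] != np.asarray(reference).size:
        if tau.shape[1] == np.asarray(reference).size:
            tau = tau.T
        else:
            raise ValueError("time axes of tau and reference do not match")
    reference = np.asarray(reference, dtype=float)
    t, R = tau.shape
    rho = np.array([spearmanr(tau[:, r], reference).statistic for r in range(R)])
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, t - 1, size=n_surrogates)
    null = np.empty((n_surrogates, R))
    for s, sh in enumerate(shifts):
        ref_s = np.roll(reference, sh)
        null[s] = [spearmanr(tau[:, r], ref_s).statistic for r in range(R)]
    lo = np.percentile(null, 2.5, axis=0)
    hi = np.percentile(null, 97.5, axis=0)
    return {
        "rho": rho,
        "rho2": rho**2,
        "lower": lo,
        "upper": hi,
        "significant": (rho < lo) | (rho > hi),
    }


def contact_similarity(vectors: np.ndarray) -> np.ndarray:
    """q x q Pearson correlation between contact vectors (rows)."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < 3:
        raise ValueError("need >= 3 channels")
    sd = vectors.std(axis=1)
    v = vectors - vectors.mean(axis=1, keepdims=True)
    v = v / np.where(sd > 0, sd, 1.0)[:, None]
    sim = (v @ v.T) / vectors.shape[1]
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def cross_matrix_correlation(
    a: np.ndarray,
    b: np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> dict:
    """Mantel-style correlation between two similarity matrices.

    Pearson correlation over upper-triangle entries; the null permutes the
    rows and columns of ``b`` simultaneously.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and same shape")
    iu = np.triu_indices_from(a, k=1)
    r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        p = rng.permutation(a.shape[0])
        bp = b[np.ix_(p, p)]
        null[s] = np.corrcoef(a[iu], bp[iu])[0, 1]
    lo, hi = np.percentile(null, [2.5, 97.5])
    return {
        "r": float(r_obs),
        "lower": float(lo),
        "upper": float(hi),
        "significant": bool(r_obs < lo or r_obs > hi),
    }


def contrast_contact_loadings(
    theta_r: np.ndarray,
    positive: np.ndarray,
    n_surrogates: int = 10_000,
    seed: int = 0,
) -> dict:
    """Unpaired t-test + Cohen's d of one component's contact loadings.

    ``surrogate_z`` = (observed d - mean shuffled d) / SD shuffled d under
    label permutation.
    """
    theta_r = np.asarray(theta_r, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.sum() == 0 or (~positive).sum() == 0:
        raise ValueError("both label groups must be non-empty")
    a, b = theta_r[positive], theta_r[~positive]
    t_stat, p = ttest_ind(a, b)
    d = cohens_d(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_surrogates)
    for s in range(n_surrogates):
        perm = rng.permutation(positive)
        null[s] = cohens_d(theta_r[perm], theta_r[~perm])
    sd = null.std()
    z = (d - null.mean()) / sd if sd > 0 else 0.0
    return {
        "t": float(t_stat),
        "p": float(p),
        "d": float(d),
        "surrogate_z": float(z),
    }
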
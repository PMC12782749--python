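"""High-level workflow: train, apply and validate the saliency model.

``fit_model`` runs the full training path (feature extraction ->
normalization -> SVD -> ranking -> consensus membership -> saliency
surface) on an interictal cohort; ``apply_model`` projects sliding-window
features of a new recording through the trained basis and surface;
``validate_tca`` runs the tensor-component cross-validation against the
model's own saliency estimates and the spike-density dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import (
    FeatureMatrix,
    extract_features,
    pool_cohort,
    sliding_window_features,
)
from .io import Recording
from .latent import (
    build_latent_space,
    normalize_feature_matrix,
    project,
    project_sliding,
)
from .model import (
    EpiNetModel,
    auc_over_time,
    build_saliency_surface,
    fit_memberships,
    global_saliency,
)
from .spikes import detect_spiky_windows, spike_density
from .tensor import (
    contact_similarity,
    correlate_time_loadings,
    cp_decompose,
    cross_matrix_correlation,
)


def extract_cohort_features(
    recordings: list[Recording],
    config: PipelineConfig,
    condition: bool = True,
) -> FeatureMatrix:
    """Per-subject feature extraction pooled into one k x q matrix."""
    return pool_cohort([extract_features(r, config, condition) for r in recordings])


def fit_model(
    recordings: list[Recording],
    config: PipelineConfig | None = None,
    seed: int = 0,
    features: FeatureMatrix | None = None,
) -> tuple[EpiNetModel, dict]:
    """Train the EpiNet-saliency model on an interictal cohort.

    Returns ``(model, info)`` where ``info`` carries the normalized
    features, coefficients, memberships and ranking diagnostics.
    """
    config = config or PipelineConfig.reduced()
    fm = features if features is not None else extract_cohort_features(recordings, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm_norm = normalize_feature_matrix(fm)
    latent = build_latent_space(
        fm_norm,
        n_shuffles=config.n_rank_shuffles,
        seed=seed,
        r=config.retained_rank,
    )
    Phi_red = project(latent.U_reduced, fm_norm.X)  # (r, q)
    pos = fm_norm.positive_mask()
    memb = fit_memberships(Phi_red, seed=seed, positive=pos)
    surface = build_saliency_surface(
        Phi_red[0], Phi_red[1], memb["consensus"], n_bins=config.saliency_bins
    )
    model = EpiNetModel(
        latent=latent,
        surface=surface,
        membership=memb["consensus"],
        config_hash=config.config_hash(),
        seed=seed,
    )
    info = {
        "features": fm,
        "features_norm": fm_norm,
        "Phi_reduced": Phi_red,
        "memberships": memb,
        "positive": pos,
    }
    return model, info


@dataclass
class SaliencyAssessment:
    """Time-resolved model output for one recording."""

    lam: np.ndarray  # (q, t) per-channel saliency
    global_saliency: np.ndarray  # (t,)
    auc: np.ndarray  # (t,) NaN if labels absent
    window_starts: np.ndarray  # seconds
    Phi: np.ndarray  # (r, q, t)
    spike_density: np.ndarray = field(default=None)  # (q, t) percent


def apply_model(
    model: EpiNetModel,
    rec: Recording,
    config: PipelineConfig | None = None,
    window_s: float | None = None,
    step_s: float | None = None,
    with_spikes: bool = True,
    features: tuple[np.ndarray, pd.DataFrame, np.ndarray] | None = None,
) -> SaliencyAssessment:
    """Assess time-resolved EpiNet saliency of a (sleep) recording.

    ``features`` may carry a precomputed ``sliding_window_features`` result
    to avoid re-extracting.
    """
    config = config or PipelineConfig.reduced()
    if features is not None:
        X_kqt, rows, starts = features
    else:
        X_kqt, rows, starts = sliding_window_features(rec, config, window_s, step_s)
    if model.latent.feature_rows is not None and len(rows) != len(
        model.latent.feature_rows
    ):
        raise ValueError("feature contract of recording does not match model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Phi = project_sliding(model.latent, X_kqt)
    lam = model.assess(Phi)
    lam = np.atleast_2d(lam)
    glob = global_saliency(lam)
    pos = rec.positive_mask()
    auc = (
        auc_over_time(lam, pos)
        if pos.any() and not pos.all()
        else np.full(lam.shape[1], np.nan)
    )
    dens = None
    if with_spikes:
        dens = _windowed_spike_density(
            rec, starts, config, window_s or config.window_s
        )
    return SaliencyAssessment(
        lam=lam,
        global_saliency=glob,
        auc=auc,
        window_starts=starts,
        Phi=Phi,
        spike_density=dens,
    )


def _windowed_spike_density(
    rec: Recording,
    starts: np.ndarray,
    config: PipelineConfig,
    window_s: float | None = None,
) -> np.ndarray:
    """Per-channel spike density (%) in each sliding window."""
    window_s = window_s or config.window_s
    out = np.zeros((rec.n_channels, starts.size))
    for ch in range(rec.n_channels):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flags = detect_spiky_windows(
                rec.data[ch], rec.fs, config.spike_window_s,
                config.spike_threshold_sd, config.spike_min_consecutive,
            )
        flag_t = np.arange(flags.size) * config.spike_window_s
        for j, t0 in enumerate(starts):
            sel = (flag_t >= t0) & (flag_t < t0 + window_s)
            out[ch, j] = spike_density(flags[sel]) if sel.any() else 0.0
    return out


def validate_tca(
    assessment: SaliencyAssessment,
    X_kqt: np.ndarray,
    positive: np.ndarray | None = None,
    R: int = 20,
    seed: int = 0,
    n_surrogates: int = 1000,
) -> dict:
    """Tensor-component validation of a saliency assessment.

    Decomposes the raw sleep feature tensor, correlates component time
    loadings with the global saliency and global spike density, builds the
    three inter-contact similarity matrices and their Mantel-style
    cross-correlations, and identifies the saliency-linked component.
    """
    X = np.asarray(X_kqt, dtype=float)
    # impute per feature before decomposition
    for i in range(X.shape[0]):
        sl = X[i]
        if not np.all(np.isfinite(sl)):
            med = np.nanmedian(sl) if np.isfinite(sl).any() else 0.0
            X[i] = np.where(np.isfinite(sl), sl, med)
    model = cp_decompose(X, R=R, seed=seed)
    corr_sal = correlate_time_loadings(
        model.tau, assessment.global_saliency, n_surrogates=n_surrogates, seed=seed
    )
    out = {"tc_model": model, "saliency_corr": corr_sal}
    if assessment.spike_density is not None:
        glob_spikes = assessment.spike_density.mean(axis=0)
        if np.ptp(glob_spikes) > 0:
            out["spike_corr"] = correlate_time_loadings(
                model.tau, glob_spikes, n_surrogates=n_surrogates, seed=seed + 1
            )
    # saliency-linked component = largest rho^2 against Lambda_hat
    best = int(np.argmax(corr_sal["rho2"]))
    out["saliency_component"] = best
    sim_tc = contact_similarity(model.theta)
    sim_lam = contact_similarity(assessment.lam)
    out["similarity"] = {"tc": sim_tc, "saliency": sim_lam}
    out["cross_correlation"] = {
        "tc_vs_saliency": cross_matrix_correlation(
            sim_tc, sim_lam, n_surrogates=n_surrogates, seed=seed + 2
        )
    }
    if assessment.spike_density is not None and np.ptp(assessment.spike_density) > 0:
        sd = assessment.spike_density
        keep = sd.std(axis=1) > 0
        if keep.sum() >= 3 and keep.all():
            sim_sp = contact_similarity(sd)
            out["similarity"]["spikes"] = sim_sp
            out["cross_correlation"]["tc_vs_spikes"] = cross_matrix_correlation(
                sim_tc, sim_sp, n_surrogates=n_surrogates, seed=seed + 3
            )
    if positive is not None:
        from .tensor import contrast_contact_loadings

        out["contact_contrast"] = contrast_contact_loadings(
            model.theta[:, best], positive, n_surrogates=min(10_000, 10 * n_surrogates),
            seed=seed + 4,
        )
    return out


def assessment_table(assessment: SaliencyAssessment, rec: Recording) -> pd.DataFrame:
    """Long-format TSV-ready table of per-channel, per-window saliency."""
    rows = []
    for j, t0 in enumerate(assessment.window_starts):
        for i, ch in enumerate(rec.channel_ids):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "channel_id": ch,
                    "window_start_s": t0,
                    "saliency": assessment.lam[i, j],
                }
            )
    return pd.DataFrame(rows)
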
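"""End-to-end feature extraction: recording -> k x q feature matrix.

The default configuration yields k = 3 criticality features x 20 bands +
4 synchrony features x 50 bands = 260 rows per channel. The row ordering
contract is criticality-first, family-major with ascending frequency
within each family (dfa@f1..fn, bis@f1..fn, fei@f1..fn, evc@g1..gm, ...);
it is frozen into the row-metadata table and into any serialized model so
projections of new data cannot silently misalign.

Bands are processed one at a time (analytic signal for all channels at one
centre frequency, features, then free), keeping peak memory proportional
to q x n_samples rather than q x n_bands x n_samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import (
    CRITICALITY_FEATURES,
    SYNCHRONY_FEATURES,
    PipelineConfig,
)
from .features_local import bistability_index, dfa_exponent, dfa_window_sizes, functional_ei
from .features_network import synchrony_features
from .io import Recording
from .preprocess import log_spaced_freqs, lowpass_and_notch, morlet_wavelet


@dataclass
class FeatureMatrix:
    """k x q feature matrix with row and column metadata."""

    X: np.ndarray  # (k, q)
    rows: pd.DataFrame  # columns: feature, frequency
    cols: pd.DataFrame  # columns: subject_id, channel_id, label

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.rows), len(self.cols)):
            raise ValueError("feature matrix shape does not match metadata")

    @property
    def k(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    def positive_mask(self) -> np.ndarray:
        from .io import is_positive_label

        return np.array([is_positive_label(l) for l in self.cols["label"]])

    def to_long(self) -> pd.DataFrame:
        """Long-format table (subject, channel, feature, frequency, value)."""
        recs = []
        for j, col in self.cols.iterrows():
            for i, row in self.rows.iterrows():
                recs.append(
                    {
                        "subject_id": col["subject_id"],
                        "channel_id": col["channel_id"],
                        "feature": row["feature"],
                        "frequency": row["frequency"],
                        "value": self.X[i, j],
                    }
                )
        return pd.DataFrame(recs)


def feature_row_table(config: PipelineConfig) -> pd.DataFrame:
    """The frozen row-ordering contract for a configuration."""
    crit_f = log_spaced_freqs(
        config.criticality_bank.fmin,
        config.criticality_bank.fmax,
        config.criticality_bank.n_freqs,
    )
    sync_f = log_spaced_freqs(
        config.synchrony_bank.fmin,
        config.synchrony_bank.fmax,
        config.synchrony_bank.n_freqs,
    )
    rows = [
        {"feature": feat, "frequency": f}
        for feat in CRITICALITY_FEATURES
        for f in crit_f
    ] + [
        {"feature": feat, "frequency": f}
        for feat in SYNCHRONY_FEATURES
        for f in sync_f
    ]
    return pd.DataFrame(rows)


def _band_analytic(
    data: np.ndarray, fs: float, freq: float, m: float
) -> tuple[np.ndarray, int]:
    """Analytic signal for all channels at one centre frequency + edge count."""
    w = morlet_wavelet(freq, m, fs)
    n = data.shape[-1]
    if len(w) > n:
        raise ValueError(
            f"recording ({n} samples) shorter than wavelet support at {freq:.2f} Hz"
        )
    coeffs = fftconvolve(data, w[None, :], mode="same", axes=-1)
    edge = min(int(np.ceil(m / freq * fs)), (n - 1) // 2)
    return coeffs, edge


def extract_features(
    rec: Recording,
    config: PipelineConfig | None = None,
    condition: bool = True,
) -> FeatureMatrix:
    """Extract the full criticality + synchrony feature matrix.

    Degenerate channels (constant signal, or fE/I outside the critical
    regime) yield NaN entries; downstream normalization imputes them with
    a logged warning.
    """
    config = config or PipelineConfig.reduced()
    fs = rec.fs
    data = lowpass_and_notch(rec.data, fs, config.filter) if condition else rec.data

    crit_f = log_spaced_freqs(
        config.criticality_bank.fmin,
        config.criticality_bank.fmax,
        config.criticality_bank.n_freqs,
    )
    sync_f = log_spaced_freqs(
        config.synchrony_bank.fmin,
        config.synchrony_bank.fmax,
        config.synchrony_bank.n_freqs,
    )
    q = rec.n_channels
    crit = {
        feat: np.full((q, len(crit_f)), np.nan) for feat in CRITICALITY_FEATURES
    }
    sync = {
        feat: np.full((q, len(sync_f)), np.nan) for feat in SYNCHRONY_FEATURES
    }

    m_crit = config.criticality_bank.morlet_m
    for i, f in enumerate(crit_f):
        coeffs, edge = _band_analytic(data, fs, f, m_crit)
        env = np.abs(coeffs[:, edge : coeffs.shape[1] - edge])
        sizes = dfa_window_sizes(
            env.shape[1], fs, config.dfa_n_windows,
            config.dfa_min_window_s, config.dfa_max_window_frac,
        )
        for ch in range(q):
            e = env[ch]
            if np.ptp(e) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dfa, _, _ = dfa_exponent(e, sizes, fs=fs)
            crit["dfa"][ch, i] = dfa
            crit["bis"][ch, i] = bistability_index(
                np.clip(e, 1e-12, None), config.bis_max_samples
            )
            try:
                crit["fei"][ch, i] = functional_ei(
                    e, fs, config.fei_window_s, config.fei_min_windows,
                    dfa_gate=config.dfa_lrtc_threshold, dfa_value=dfa,
                )
            except ValueError:
                pass  # too few windows: leave NaN

    m_sync = config.synchrony_bank.morlet_m
    if q >= 2:
        for i, f in enumerate(sync_f):
            coeffs, edge = _band_analytic(data, fs, f, m_sync)
            phases = np.angle(coeffs[:, edge : coeffs.shape[1] - edge])
            from .features_network import plv_matrix

            feats = synchrony_features(plv_matrix(phases))
            for name in SYNCHRONY_FEATURES:
                sync[name][:, i] = feats[name]

    blocks = [crit[f] for f in CRITICALITY_FEATURES] + [
        sync[f] for f in SYNCHRONY_FEATURES
    ]
    X = np.concatenate(blocks, axis=1).T  # (k, q)
    cols = pd.DataFrame(
        {
            "subject_id": rec.subject_id,
            "channel_id": rec.channel_ids,
            "label": rec.labels,
        }
    )
    return FeatureMatrix(X=X, rows=feature_row_table(config), cols=cols)


def pool_cohort(mats: list[FeatureMatrix]) -> FeatureMatrix:
    """Pool per-subject feature matrices column-wise (shared row contract)."""
    if not mats:
        raise ValueError("no feature matrices to pool")
    ref = mats[0].rows
    for m in mats[1:]:
        if not np.allclose(m.rows["frequency"], ref["frequency"]) or list(
            m.rows["feature"]
        ) != list(ref["feature"]):
            raise ValueError("feature row contracts differ between subjects")
    return FeatureMatrix(
        X=np.concatenate([m.X for m in mats], axis=1),
        rows=ref.copy(),
        cols=pd.concat([m.cols for m in mats], ignore_index=True),
    )


def n_sliding_windows(duration_s: float, window_s: float, step_s: float) -> int:
    """t = floor((duration - window) / step) + 1."""
    if duration_s < window_s:
        raise ValueError("recording shorter than the analysis window")
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def sliding_window_features(
    rec: Recording,
    config: PipelineConfig | None = None,
    window_s: float | None = None,
    step_s: float | None = None,
    condition: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Time-resolved feature tensor X (k, q, t) over a sliding window.

    Returns ``(X_kqt, row_table, window_start_times)``. The full feature
    pipeline runs independently per window.
    """
    config = config or PipelineConfig.reduced()
    window_s = config.window_s if window_s is None else window_s
    step_s = config.step_s if step_s is None else step_s
    t = n_sliding_windows(rec.duration, window_s, step_s)
    starts = np.arange(t) * step_s
    mats = []
    for t0 in starts:
        seg = rec.segment(t0, t0 + window_s)
        mats.append(extract_features(seg, config, condition=condition))
    X = np.stack([m.X for m in mats], axis=2)
    return X, mats[0].rows, starts
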
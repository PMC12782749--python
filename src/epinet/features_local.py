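"""Per-channel criticality features on narrowband amplitude envelopes.

Three estimators, each computed per (channel, frequency band):

* **DFA exponent** — slope of the log-log least-squares fit of the RMS
  detrended fluctuation of the cumulative demeaned envelope against window
  size. Exponents above 0.6 indicate significant long-range temporal
  correlations (operation inside the extended critical, Griffiths-phase
  regime); white-noise envelopes give 0.5.

* **Bistability index (BiS)** — evidence for a two-state amplitude
  distribution: the Bayesian-information-criterion difference between a
  two-component and a one-component Gaussian mixture fitted to the
  log-envelope, scaled per sample. Positive values support bimodality and
  grow with mode separation; unimodal envelopes give values <= 0.

* **Functional E/I (fE/I)** — 1 - r, where r is the correlation across
  time windows between the mean window amplitude and the
  amplitude-normalized detrended window fluctuation. Values below 1 mark
  inhibition-dominant dynamics (fluctuations suppressed at high
  amplitude), above 1 excitation-dominant. The estimator is defined only
  in the critical regime and returns NaN when the envelope's DFA exponent
  is at or below the LRTC threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.mixture import GaussianMixture

from .config import PipelineConfig


def dfa_window_sizes(
    n_samples: int,
    fs: float,
    n_windows: int = 16,
    min_window_s: float = 1.0,
    max_window_frac: float = 0.1,
) -> np.ndarray:
    """Log-spaced DFA window sizes between 1 s and a fraction of the segment."""
    lo = max(8, int(round(min_window_s * fs)))
    hi = max(lo + 1, int(n_samples * max_window_frac))
    sizes = np.unique(
        np.round(np.logspace(np.log10(lo), np.log10(hi), n_windows)).astype(int)
    )
    return sizes


def dfa_exponent(
    envelope: np.ndarray,
    window_sizes: np.ndarray | None = None,
    fs: float = 1000.0,
    config: PipelineConfig | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Detrended fluctuation analysis of an amplitude envelope.

    Returns ``(exponent, window_sizes, fluctuations)``. The profile is the
    cumulative sum of the demeaned envelope; each non-overlapping window is
    linearly detrended and the RMS residual pooled across windows gives the
    fluctuation F(s); the exponent is the least-squares slope of
    log10 F(s) vs log10 s. Constant envelopes are degenerate and yield NaN.
    """
    envelope = np.asarray(envelope, dtype=float)
    if config is not None and window_sizes is None:
        window_sizes = dfa_window_sizes(
            envelope.size, fs, config.dfa_n_windows,
            config.dfa_min_window_s, config.dfa_max_window_frac,
        )
    elif window_sizes is None:
        window_sizes = dfa_window_sizes(envelope.size, fs)
    window_sizes = np.asarray(window_sizes, dtype=int)
    if window_sizes.size < 4:
        raise ValueError("need at least 4 DFA window sizes")
    if envelope.size < 4 * window_sizes.max():
        raise ValueError("envelope shorter than 4x the largest DFA window")
    if np.ptp(envelope) == 0:
        warnings.warn("constant envelope: DFA undefined, returning NaN")
        return float("nan"), window_sizes, np.full(window_sizes.size, np.nan)

    profile = np.cumsum(envelope - envelope.mean())
    flucts = np.empty(window_sizes.size)
    for i, s in enumerate(window_sizes):
        n_win = profile.size // s
        seg = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s)
        # vectorized per-window linear detrend
        t_mean = t.mean()
        t_var = ((t - t_mean) ** 2).sum()
        seg_mean = seg.mean(axis=1, keepdims=True)
        slope = ((seg - seg_mean) @ (t - t_mean))[:, None] / t_var
        resid = seg - seg_mean - slope * (t - t_mean)
        flucts[i] = np.sqrt(np.mean(resid**2))
    log_s, log_f = np.log10(window_sizes), np.log10(flucts)
    exponent = np.polyfit(log_s, log_f, 1)[0]
    return float(exponent), window_sizes, flucts


def bistability_index(
    envelope: np.ndarray,
    max_samples: int = 2000,
    seed: int = 0,
) -> float:
    """BiS: per-sample BIC evidence for a bimodal log-envelope distribution.

    BiS = (BIC_1comp - BIC_2comp) / n over a deterministic subsample of the
    log-envelope; positive values support a two-state distribution.
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope <= 0):
        raise ValueError("envelope must be strictly positive (log undefined)")
    log_env = np.log(envelope)
    if log_env.size > max_samples:
        idx = np.linspace(0, log_env.size - 1, max_samples).astype(int)
        log_env = log_env[idx]
    x = log_env[:, None]
    if np.ptp(x) == 0:
        return 0.0
    bic = []
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed,
            n_init=1, max_iter=200, reg_covar=1e-6,
        )
        gm.fit(x)
        bic.append(gm.bic(x))
    return float((bic[0] - bic[1]) / x.shape[0])


def functional_ei(
    envelope: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    min_windows: int = 20,
    dfa_gate: float | None = 0.6,
    dfa_value: float | None = None,
) -> float:
    """Functional E/I index of a narrowband amplitude envelope.

    Splits the envelope into non-overlapping windows; per window computes
    the mean amplitude and the detrended fluctuation of the cumulative
    profile of the amplitude-normalized window. fE/I = 1 - r between the
    two across windows. Returns NaN (flagged undefined) when the envelope
    is not in the critical regime (DFA <= ``dfa_gate``).
    """
    envelope = np.asarray(envelope, dtype=float)
    s = int(round(window_s * fs))
    n_win = envelope.size // s
    if n_win < min_windows:
        raise ValueError(
            f"only {n_win} windows of {window_s} s; need >= {min_windows}"
        )
    if dfa_gate is not None:
        if dfa_value is None:
            dfa_value = dfa_exponent(envelope, fs=fs)[0]
        if not np.isfinite(dfa_value) or dfa_value <= dfa_gate:
            return float("nan")

    seg = envelope[: n_win * s].reshape(n_win, s)
    mean_amp = seg.mean(axis=1)
    if np.any(mean_amp <= 0):
        return float("nan")
    norm = seg / mean_amp[:, None]
    profile = np.cumsum(norm - norm.mean(axis=1, keepdims=True), axis=1)
    t = np.arange(s)
    t_mean = t.mean()
    t_var = ((t - t_mean) ** 2).sum()
    pm = profile.mean(axis=1, keepdims=True)
    slope = ((profile - pm) @ (t - t_mean))[:, None] / t_var
    resid = profile - pm - slope * (t - t_mean)
    fluct = np.sqrt(np.mean(resid**2, axis=1))
    if np.std(mean_amp) == 0 or np.std(fluct) == 0:
        return 1.0
    r = np.corrcoef(mean_amp, fluct)[0, 1]
    return float(1.0 - r)


def collapse_bands(
    values: np.ndarray,
    freqs: np.ndarray,
    clusters: dict[str, tuple[float, float]],
) -> tuple[np.ndarray, list[str]]:
    """Average narrowband feature values into named frequency clusters.

    ``values`` has frequencies on its last axis; frequencies outside every
    cluster are dropped. Returns (collapsed values, cluster names).
    """
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if values.shape[-1] != freqs.size:
        raise ValueError("last axis of values must match freqs")
    names, out = [], []
    for name, (lo, hi) in clusters.items():
        mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"cluster {name!r} ({lo}-{hi} Hz) maps no frequency")
        names.append(name)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append(np.nanmean(values[..., mask], axis=-1))
    return np.stack(out, axis=-1), names
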
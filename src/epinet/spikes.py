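"""Interictal-spike detection, spike density, and spike-phase analyses.

A broadband channel is split into non-overlapping 0.5 s windows; a window
is "spiky" if at least three consecutive samples exceed the channel mean
plus seven standard deviations (statistics taken over the whole session).
Spike density is the percentage of spiky windows. The phase of the slow
fluctuation of the channel-mean density is extracted with the Hilbert
transform after demeaning and smoothing, and label contrasts of saliency
can be resolved into four 90-degree spike-phase bins against
label-shuffled surrogates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import hilbert


def detect_spiky_windows(
    x: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    threshold_sd: float = 7.0,
    min_consecutive: int = 3,
) -> np.ndarray:
    """Boolean flag per 0.5 s window: does it contain a spike transient?

    The threshold is one-sided (positive excursions) and relative to the
    session mean and SD of the channel, so detection is invariant to
    amplitude scaling. Trailing partial windows are truncated.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    n_win = x.size // w
    if n_win < 1:
        raise ValueError("signal shorter than one window")
    sd = x.std()
    if sd == 0:
        warnings.warn("zero-variance channel: no spiky windows")
        return np.zeros(n_win, dtype=bool)
    above = (x[: n_win * w] > x.mean() + threshold_sd * sd).reshape(n_win, w)
    if min_consecutive <= 1:
        return above.any(axis=1)
    if above.shape[1] < min_consecutive:
        return np.zeros(n_win, dtype=bool)
    # rolling sum over min_consecutive samples; a full-count run means a spike
    c = np.cumsum(above, axis=1)
    k = min_consecutive
    window_sums = np.concatenate([c[:, k - 1 : k], c[:, k:] - c[:, :-k]], axis=1)
    return window_sums.max(axis=1) >= k


def spike_density(flags: np.ndarray) -> float:
    """Percentage of windows flagged spiky."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size < 1:
        raise ValueError("need at least one window")
    return 100.0 * flags.mean()


def spike_density_per_channel(
    data: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    threshold_sd: float = 7.0,
    min_consecutive: int = 3,
) -> np.ndarray:
    """Spike density (%) for each channel of a (q, n) array."""
    return np.array(
        [
            spike_density(
                detect_spiky_windows(ch, fs, window_s, threshold_sd, min_consecutive)
            )
            for ch in np.atleast_2d(data)
        ]
    )


def global_spike_phase(
    density: np.ndarray,
    dt: float,
    smooth_s: float | None = 600.0,
) -> np.ndarray:
    """Instantaneous phase of the slow fluctuation of global spike density.

    The series is demeaned (and, by default, smoothed with a 10 min moving
    average) before the analytic signal is formed, so phase 0 falls at the
    local maxima of a cosine-like fluctuation.
    """
    density = np.asarray(density, dtype=float)
    if np.ptp(density) == 0:
        raise ValueError("constant density series: phase undefined")
    y = density - density.mean()
    if smooth_s is not None and smooth_s > dt:
        from scipy.ndimage import uniform_filter1d

        y = uniform_filter1d(y, size=min(int(round(smooth_s / dt)), y.size), mode="nearest")
        y = y - y.mean()
    if np.ptp(y) == 0:
        raise ValueError("density series constant after smoothing")
    return np.angle(hilbert(y))


PHASE_BIN_EDGES = np.deg2rad([-180.0, -90.0, 0.0, 90.0, 180.0])


def phase_binned_effect_sizes(
    saliency: np.ndarray,
    phases: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 4,
    n_surrogates: int = 1000,
    seed: int = 0,
) -> dict:
    """Label contrast of saliency resolved into 90-degree spike-phase bins.

    Parameters
    ----------
    saliency : (q, t) per-channel saliency samples
    phases : (t,) global spike-density phase per time point, in (-pi, pi]
    labels : (q,) boolean, True = positive class

    Returns a dict with per-bin Cohen's d and 2.5/97.5 percentile bounds
    from label-shuffled surrogates. Empty bins yield NaN with a warning.
    """
    saliency = np.atleast_2d(np.asarray(saliency, dtype=float))
    phases = np.asarray(phases, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if n_bins != 4:
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    else:
        edges = PHASE_BIN_EDGES
    # right-closed bins covering (-180, 180]
    bin_idx = np.clip(np.searchsorted(edges, phases, side="left") - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    d_obs = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    for b in range(n_bins):
        cols = bin_idx == b
        if not cols.any():
            warnings.warn(f"phase bin {b} is empty")
            continue
        block = saliency[:, cols]
        d_obs[b] = cohens_d(block[labels].ravel(), block[~labels].ravel())
        null = np.empty(n_surrogates)
        for s in range(n_surrogates):
            perm = rng.permutation(labels)
            null[s] = cohens_d(block[perm].ravel(), block[~perm].ravel())
        lo[b], hi[b] = np.percentile(null, [2.5, 97.5])
    return {"d": d_obs, "lower": lo, "upper": hi, "bin_edges": edges}


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled (n-1) sample SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return float("nan")
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)
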
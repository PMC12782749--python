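"""Synthetic multichannel recordings with planted epileptogenic structure.

Real interictal SEEG cannot be shared, so the pipeline is exercised on
surrogate cohorts whose generating parameters are known exactly. Each
channel is an amplitude-modulated narrowband oscillation on a pink-noise
background:

* long-range temporal correlations — the slow amplitude envelope is
  fractional Gaussian noise with a chosen Hurst exponent, synthesized
  spectrally (power spectrum ~ f**(1-2H)), so the DFA exponent of the
  narrowband envelope has an analytically known target;
* bistability — the envelope is multiplied by a smoothed two-state
  telegraph process whose level ratio controls histogram bimodality;
* E/I regime — fast envelope fluctuations are gain-modulated by the local
  mean amplitude (positive exponent: excitation-dominant, fluctuations grow
  with amplitude; negative: inhibition-dominant), matching the functional
  E/I estimator's construction;
* synchrony — channels in the same coupling group mix a shared narrowband
  phase driver into their carrier at ``coupling_strength``, so within-group
  phase locking rises monotonically with the planted coupling;
* interictal spikes — high-amplitude transients (<200 ms) at Poisson times.

"Sleep" cohorts additionally modulate the pathological channels with an
ultradian envelope (sinusoid plus slow noise, period minutes to hours); that
envelope is stored as the per-channel ground-truth saliency trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Recording

CARRIER_HZ = 10.0  # narrowband carrier / phase-driver frequency


@dataclass(frozen=True)
class ChannelSpec:
    """Generating parameters of one synthetic channel."""

    hurst_exponent: float = 0.6  # envelope LRTC target, in (0.5, 1)
    bistability_level: float = 0.0  # high/low envelope ratio = 1 + level
    ei_regime: str = "balanced"  # inhibition | balanced | excitation
    ei_strength: float = 1.0  # scales the E/I gain coupling, in [0, 1]
    coupling_group: int = 0  # channels sharing a phase driver
    coupling_strength: float = 0.0  # in [0, 1]
    spike_rate: float = 0.0  # events / minute
    label: str = "nonEpiNet"

    def __post_init__(self) -> None:
        if not (0.5 < self.hurst_exponent < 1.0):
            raise ValueError("hurst_exponent must lie in (0.5, 1.0)")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.spike_rate < 0 or self.bistability_level < 0:
            raise ValueError("spike_rate and bistability_level must be >= 0")
        if self.ei_regime not in ("inhibition", "balanced", "excitation"):
            raise ValueError(f"unknown ei_regime {self.ei_regime!r}")
        if not (0.0 <= self.ei_strength <= 1.0):
            raise ValueError("ei_strength must lie in [0, 1]")


def epinet_channel_spec(group: int = 1) -> ChannelSpec:
    """Strong-contrast pathological channel (planted EpiNet defaults)."""
    return ChannelSpec(
        hurst_exponent=0.85,
        bistability_level=3.0,
        ei_regime="inhibition",
        coupling_group=group,
        coupling_strength=0.8,
        spike_rate=3.0,
        label="EpiNet",
    )


def nonepinet_channel_spec(group: int = 2) -> ChannelSpec:
    """Background channel: weak LRTCs, unimodal, weakly coupled, few spikes."""
    return ChannelSpec(
        hurst_exponent=0.6,
        bistability_level=0.0,
        ei_regime="balanced",
        coupling_group=group,
        coupling_strength=0.1,
        spike_rate=0.2,
        label="nonEpiNet",
    )


def graded_channel_spec(contrast: float, group: int = 1) -> ChannelSpec:
    """EpiNet channel with parameters interpolated toward background.

    ``contrast`` in [0, 1]: 0 reproduces the background defaults, 1 the
    strong-contrast EpiNet defaults. Used to build cohorts with graded
    pathology for saliency-accuracy coupling analyses.
    """
    if not (0.0 <= contrast <= 1.0):
        raise ValueError("contrast must lie in [0, 1]")
    return ChannelSpec(
        hurst_exponent=0.6 + 0.25 * contrast,
        bistability_level=3.0 * contrast,
        ei_regime="inhibition" if contrast > 0 else "balanced",
        ei_strength=contrast,
        coupling_group=group,
        coupling_strength=0.1 + 0.7 * contrast,
        spike_rate=0.2 + 2.8 * contrast,
        label="EpiNet",
    )


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 6
    channels_per_subject: int = 20
    duration: float = 600.0  # seconds
    sampling_rate: float = 1000.0  # Hz
    ultradian_period: float = 90.0  # minutes, sleep mode only
    epinet_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.channels_per_subject < 1:
            raise ValueError("cohort must have >= 1 subject and channel")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")


@dataclass
class GroundTruth:
    """Planted per-channel truth for one cohort."""

    labels: pd.DataFrame  # subject_id, channel_id, label
    spike_times: dict[tuple[str, str], np.ndarray]  # seconds
    saliency_times: np.ndarray  # seconds, shared time axis
    saliency: dict[str, np.ndarray]  # subject_id -> (n_channels, n_times)
    meta: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_fgn(hurst: float, n: int, seed=0) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (Davies-Harte).

    Samples from the exact fGn autocovariance
    gamma(k) = 0.5 * (|k+1|**2H - 2|k|**2H + |k-1|**2H),
    giving a stationary zero-mean, unit-variance series whose DFA exponent
    converges to ``hurst``. Falls back to spectral synthesis
    (power spectrum ~ f**(1-2H)) in the rare case the circulant embedding
    is not non-negative definite.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    if n == 1:
        return np.zeros(1)
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(circ).real
    m = circ.size
    if np.min(lam) < -1e-9 * np.max(lam):
        x = _fgn_spectral(hurst, n, rng)
    else:
        lam = np.clip(lam, 0.0, None)
        nf = lam.size
        z = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
        z[0] = z[0].real * np.sqrt(2)
        if m % 2 == 0:
            z[-1] = z[-1].real * np.sqrt(2)
        x = np.fft.irfft(z * np.sqrt(lam * m / 2.0), n=m)[:n]
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _fgn_spectral(hurst: float, n: int, rng) -> np.ndarray:
    nf = n // 2 + 1
    f = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros(nf)
    amp[1:] = f[1:] ** ((1.0 - 2.0 * hurst) / 2.0)
    spec = amp * (rng.standard_normal(nf) + 1j * rng.standard_normal(nf))
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    return np.fft.irfft(spec, n=n)


def generate_bistable_envelope(
    low_level: float,
    high_level: float,
    switch_rate: float,
    n: int,
    seed=0,
    fs: float = 1000.0,
    smooth_s: float = 0.25,
) -> np.ndarray:
    """Smoothed two-state telegraph envelope.

    State dwell times are exponential with mean 1/switch_rate; the binary
    level series is smoothed with a moving average of ``smooth_s`` seconds.
    With well-separated levels the amplitude histogram is bimodal.
    """
    if not (high_level >= low_level > 0):
        raise ValueError("need high_level >= low_level > 0")
    if switch_rate <= 0:
        raise ValueError("switch_rate must be positive")
    rng = _rng(seed)
    env = np.empty(n)
    state = bool(rng.integers(2))
    i = 0
    while i < n:
        dwell = max(1, int(round(rng.exponential(1.0 / switch_rate) * fs)))
        env[i : i + dwell] = high_level if state else low_level
        state = not state
        i += dwell
    return _smooth(env, max(1, int(round(smooth_s * fs))))


def _smooth(x: np.ndarray, k: int) -> np.ndarray:
    """Running mean with edge replication (O(n) regardless of k)."""
    if k <= 1:
        return x
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(x, size=min(k, x.size), mode="nearest")


# Exponent coupling the relative fast-fluctuation gain to the local mean
# amplitude. Excitation-dominant dynamics saturate: relative fluctuations
# shrink at high amplitude (negative exponent -> amplitude/normalized-
# fluctuation correlation r < 0 -> fE/I = 1 - r > 1). Inhibition-dominant
# dynamics show the opposite, giving fE/I < 1.
_EI_EXPONENT = {"inhibition": 3.0, "balanced": 0.0, "excitation": -3.0}


def _channel_envelope(spec: ChannelSpec, n: int, fs: float, rng) -> np.ndarray:
    """Positive amplitude envelope with planted H, bistability and E/I.

    The base envelope is log-normal, exp(0.35 * fGn(H)): multiplicative,
    so the unimodal log-envelope is Gaussian (BiS <= 0 by construction)
    and relative fluctuations are amplitude-independent in the balanced
    regime.
    """
    m = np.exp(0.35 * generate_fgn(spec.hurst_exponent, n, rng))
    if spec.bistability_level > 0:
        m = m * generate_bistable_envelope(
            1.0, 1.0 + spec.bistability_level, 0.1, n, rng, fs=fs, smooth_s=0.25
        )
    # fast multiplicative fluctuations, gain-coupled to local mean amplitude
    kappa = _EI_EXPONENT[spec.ei_regime] * spec.ei_strength
    fast = generate_fgn(0.7, n, rng)
    fast = fast - _smooth(fast, int(5 * fs))  # keep only sub-5 s structure
    local = _smooth(m, int(5 * fs))
    gain = (local / local.mean()) ** kappa
    # additive fast term keeps the window mean unbiased by the gain; the
    # floor only guards positivity in rare large excursions
    return m * np.maximum(1.0 + 0.3 * fast * gain, 0.05)


def _jittered_phase(n: int, fs: float, rng, f0: float = CARRIER_HZ) -> np.ndarray:
    """Carrier phase with ~2% correlated frequency jitter (phase diffusion)."""
    jitter = _smooth(rng.standard_normal(n), int(fs))  # ~1 s correlation time
    sd = jitter.std()
    if sd > 0:
        jitter = jitter / sd
    inst_f = f0 * (1.0 + 0.05 * jitter)
    return 2 * np.pi * np.cumsum(inst_f) / fs + rng.uniform(0, 2 * np.pi)


def generate_coupled_channels(
    specs: list[ChannelSpec],
    duration: float,
    fs: float,
    seed=0,
    subject_id: str = "sub-00",
    noise_level: float = 0.25,
) -> tuple[Recording, GroundTruth]:
    """Synthesize one subject's recording from per-channel specs.

    Channels sharing a ``coupling_group`` mix a common phase driver into
    their carrier at their ``coupling_strength``; the within-group
    phase-locking value rises monotonically with that strength.
    """
    if len(specs) < 1:
        raise ValueError("need at least one channel spec")
    n = int(round(duration * fs))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    drv_ss, *ch_ss = ss.spawn(len(specs) + 1)
    drv_rng = np.random.default_rng(drv_ss)
    groups = sorted({s.coupling_group for s in specs})
    driver_phase = {
        g: _jittered_phase(n, fs, np.random.default_rng(drv_rng.integers(2**31)))
        for g in groups
    }

    data = np.empty((len(specs), n))
    spike_times: dict[tuple[str, str], np.ndarray] = {}
    channel_ids = [f"ch{idx:03d}" for idx in range(len(specs))]
    for idx, (spec, sub_ss) in enumerate(zip(specs, ch_ss)):
        rng = np.random.default_rng(sub_ss)
        env = _channel_envelope(spec, n, fs, rng)
        own = _jittered_phase(n, fs, rng)
        c = spec.coupling_strength
        carrier = (1.0 - c) * np.cos(own) + c * np.cos(driver_phase[spec.coupling_group])
        background = noise_level * generate_fgn(0.55, n, rng)
        x = env * carrier + background
        x, times = inject_spikes(x, spec.spike_rate, 10.0, rng, fs=fs)
        data[idx] = x
        spike_times[(subject_id, channel_ids[idx])] = times

    labels = pd.DataFrame(
        {
            "subject_id": subject_id,
            "channel_id": channel_ids,
            "label": [s.label for s in specs],
        }
    )
    rec = Recording(
        data,
        fs,
        subject_id,
        channel_ids,
        [s.label for s in specs],
        meta={"seed": str(ss.entropy), "generator": "epinet.synth"},
    )
    sal_times = np.arange(0.0, duration, 1.0)
    sal = np.where(
        np.array([s.label == "EpiNet" for s in specs])[:, None],
        1.0,
        0.0,
    ) * np.ones((len(specs), len(sal_times)))
    gt = GroundTruth(
        labels=labels,
        spike_times=spike_times,
        saliency_times=sal_times,
        saliency={subject_id: sal},
    )
    return rec, gt


def spike_waveform(fs: float, amplitude: float, width_s: float = 0.03) -> np.ndarray:
    """Flat-topped positive transient: amplitude * exp(-(t/width)^4 / 2).

    Support +-2*width (120 ms by default, under the 200 ms transient bound);
    the flat top guarantees several consecutive suprathreshold samples even
    at low sampling rates.
    """
    half = int(np.ceil(2 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    return amplitude * np.exp(-((t / width_s) ** 4) / 2.0)


def inject_spikes(
    x: np.ndarray,
    rate: float,
    amplitude_sd: float,
    seed=0,
    fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add epileptiform transients at Poisson times; returns (signal, times).

    ``amplitude_sd`` scales the transient peak in units of the baseline
    standard deviation of ``x``. Rate 0 returns the signal unchanged.
    """
    if rate < 0 or amplitude_sd < 0:
        raise ValueError("rate and amplitude must be >= 0")
    x = np.asarray(x, dtype=float)
    if rate == 0:
        return x.copy(), np.empty(0)
    rng = _rng(seed)
    duration = x.size / fs
    n_spikes = rng.poisson(rate * duration / 60.0)
    if n_spikes == 0:
        return x.copy(), np.empty(0)
    times = np.sort(rng.uniform(0.1, duration - 0.1, size=n_spikes))
    w = spike_waveform(fs, amplitude_sd * x.std())
    half = len(w) // 2
    y = x.copy()
    for t in times:
        i = int(round(t * fs))
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        y[lo:hi] += w[half - (i - lo) : half + (hi - i)]
    return y, times


def ultradian_envelope(
    duration: float, period_minutes: float, rng, dt: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Saliency modulation s(t) in [0, 1]: sinusoid plus slow noise."""
    t = np.arange(0.0, duration, dt)
    phase = rng.uniform(0, 2 * np.pi)
    slow = _smooth(rng.standard_normal(t.size), max(1, int(period_minutes * 60 / dt / 8)))
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    s = 0.5 + 0.45 * np.sin(2 * np.pi * t / (period_minutes * 60.0) + phase) + 0.1 * slow
    return t, np.clip(s, 0.0, 1.0)


def perturb_channel_spec(
    spec: ChannelSpec, rng, scale: float = 1.0
) -> ChannelSpec:
    """Per-channel biological variability around nominal parameters.

    Real contacts are heterogeneous: without channel-level parameter
    jitter every channel estimates its nominal value almost exactly and
    even minute group offsets become perfectly classifiable. Jitter is
    correlated across features of a channel by construction (one channel,
    one parameter draw).
    """
    h = float(np.clip(spec.hurst_exponent + scale * 0.08 * rng.standard_normal(), 0.55, 0.95))
    bist = float(
        max(0.0, spec.bistability_level * np.exp(scale * 0.5 * rng.standard_normal())
            + scale * abs(0.4 * rng.standard_normal()))
    )
    coup = float(np.clip(spec.coupling_strength + scale * 0.12 * rng.standard_normal(), 0.0, 1.0))
    rate = float(spec.spike_rate * np.exp(scale * 0.5 * rng.standard_normal()))
    ei = float(np.clip(spec.ei_strength + scale * 0.2 * rng.standard_normal(), 0.0, 1.0))
    return replace(
        spec, hurst_exponent=h, bistability_level=bist,
        coupling_strength=coup, spike_rate=rate, ei_strength=ei,
    )


def _subject_specs(cohort: CohortSpec, rng) -> list[ChannelSpec]:
    q = cohort.channels_per_subject
    n_epi = int(round(cohort.epinet_fraction * q))
    specs = [epinet_channel_spec(group=1) for _ in range(n_epi)]
    specs += [nonepinet_channel_spec(group=2 + i // 4) for i in range(q - n_epi)]
    return [perturb_channel_spec(sp, rng) for sp in specs]


def generate_cohort(
    cohort: CohortSpec,
    channel_specs: list[list[ChannelSpec]] | None = None,
    mode: str = "interictal",
) -> tuple[list[Recording], GroundTruth]:
    """Generate a cohort of synthetic subjects with ground truth.

    ``mode="interictal"`` yields stationary recordings (>=10 min per subject
    under the default spec). ``mode="sleep"`` crossfades each pathological
    channel between background-like and EpiNet-like dynamics under the
    ultradian envelope, which is stored as the true saliency trace.
    """
    if mode not in ("interictal", "sleep"):
        raise ValueError(f"unknown mode {mode!r}")
    if channel_specs is not None and len(channel_specs) != cohort.n_subjects:
        raise ValueError("channel_specs must have one list per subject")
    master = np.random.SeedSequence(cohort.seed)
    sub_seeds = master.spawn(cohort.n_subjects)
    recs: list[Recording] = []
    all_labels = []
    spike_times: dict[tuple[str, str], np.ndarray] = {}
    saliency: dict[str, np.ndarray] = {}
    sal_times = np.arange(0.0, cohort.duration, 1.0)

    for s_idx, sub_ss in enumerate(sub_seeds):
        subject_id = f"sub-{s_idx:02d}"
        spec_rng = np.random.default_rng(sub_ss.spawn(1)[0])
        specs = (
            channel_specs[s_idx]
            if channel_specs is not None
            else _subject_specs(cohort, spec_rng)
        )
        if mode == "interictal":
            rec, gt = generate_coupled_channels(
                specs, cohort.duration, cohort.sampling_rate,
                seed=sub_ss, subject_id=subject_id,
            )
            sal = gt.saliency[subject_id]
        else:
            rec, sal = _sleep_subject(specs, cohort, sub_ss, subject_id, spike_times)
            gt = None
        if gt is not None:
            spike_times.update(gt.spike_times)
        recs.append(rec)
        all_labels.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "channel_id": rec.channel_ids,
                    "label": rec.labels,
                }
            )
        )
        saliency[subject_id] = sal

    gt = GroundTruth(
        labels=pd.concat(all_labels, ignore_index=True),
        spike_times=spike_times,
        saliency_times=sal_times,
        saliency=saliency,
        meta={"mode": mode, "seed": cohort.seed},
    )
    return recs, gt


def _sleep_subject(
    specs: list[ChannelSpec],
    cohort: CohortSpec,
    sub_ss: np.random.SeedSequence,
    subject_id: str,
    spike_times: dict,
) -> tuple[Recording, np.ndarray]:
    """Sleep-mode subject: EpiNet channels crossfade under the ultradian drive."""
    fs = cohort.sampling_rate
    n = int(round(cohort.duration * fs))
    env_ss, epi_ss, bg_ss = sub_ss.spawn(3)
    t_sal, s = ultradian_envelope(
        cohort.duration, cohort.ultradian_period, np.random.default_rng(env_ss)
    )
    s_full = np.interp(np.arange(n) / fs, t_sal, s)

    # Two parallel synthesized versions of the subject: pathological
    # channels crossfade between their background twin and their EpiNet
    # dynamics; spike trains are thinned by the same envelope.
    base_specs = [
        replace(
            nonepinet_channel_spec(group=2 + i),
            label=sp.label,
        )
        for i, sp in enumerate(specs)
    ]
    epi_specs = [replace(sp, spike_rate=0.0) for sp in specs]
    base_specs_ns = [replace(sp, spike_rate=0.0) for sp in base_specs]
    rec_epi, _ = generate_coupled_channels(
        epi_specs, cohort.duration, fs, seed=epi_ss, subject_id=subject_id
    )
    rec_bg, _ = generate_coupled_channels(
        base_specs_ns, cohort.duration, fs, seed=bg_ss, subject_id=subject_id
    )
    is_epi = np.array([sp.label == "EpiNet" for sp in specs])
    # Amplitude crossfading is strongly convex in the downstream feature
    # response (synchrony and LRTC features of a mixture are dominated by
    # the pathological component well below equal weight). Squaring the
    # envelope makes the planted saliency trace map roughly linearly onto
    # feature contrast instead of saturating early in the cycle.
    mix = np.where(is_epi[:, None], s_full[None, :] ** 2, 0.0)
    data = (1.0 - mix) * rec_bg.data + mix * rec_epi.data

    # spikes: inhomogeneous Poisson, rate modulated by the saliency envelope
    spike_rng = np.random.default_rng(sub_ss.spawn(1)[0])
    for idx, sp in enumerate(specs):
        rate_t = sp.spike_rate * (s if is_epi[idx] else np.ones_like(s))
        times = _inhomogeneous_poisson(rate_t, t_sal, spike_rng)
        w = spike_waveform(fs, 10.0 * data[idx].std())
        half = len(w) // 2
        for t in times:
            i = int(round(t * fs))
            lo, hi = max(0, i - half), min(n, i + half + 1)
            data[idx, lo:hi] += w[half - (i - lo) : half + (hi - i)]
        spike_times[(subject_id, f"ch{idx:03d}")] = times

    rec = Recording(
        data,
        fs,
        subject_id,
        [f"ch{idx:03d}" for idx in range(len(specs))],
        [sp.label for sp in specs],
        meta={"mode": "sleep", "ultradian_period_min": cohort.ultradian_period},
    )
    sal = np.where(is_epi[:, None], s[None, :], 0.0)
    return rec, sal


def _inhomogeneous_poisson(rate_per_min, t, rng) -> np.ndarray:
    """Thinning sampler; ``rate_per_min`` given on time grid ``t`` (s)."""
    rmax = float(np.max(rate_per_min))
    if rmax <= 0:
        return np.empty(0)
    duration = t[-1] if len(t) else 0.0
    n_cand = rng.poisson(rmax * duration / 60.0)
    cand = np.sort(rng.uniform(0.1, max(duration - 0.1, 0.1), size=n_cand))
    keep = rng.uniform(0, rmax, size=n_cand) < np.interp(cand, t, rate_per_min)
    return cand[keep]
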
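"""Pipeline configuration.

All analysis settings live in one dataclass so that a run can be serialized,
hashed and replayed. The :meth:`PipelineConfig.default` preset mirrors the
clinical analysis configuration (1 kHz sampling, 20 criticality bands from
2-225 Hz, 50 synchrony bands from 2-450 Hz, 10 min windows). The
:meth:`PipelineConfig.reduced` preset keeps every structural choice but
shrinks band counts, sampling rate and window lengths so that full-pipeline
runs finish in seconds; it is the preset used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class FilterSettings:
    """Broadband FIR conditioning: low-pass plus line-noise notches."""

    lowpass_cutoff: float = 440.0  # Hz, passband edge
    lowpass_stop: float = 500.0  # Hz, stopband edge
    transition: float = 60.0  # Hz
    passband_ripple: float = 0.02  # fraction
    notch_base: float = 50.0  # Hz line frequency; harmonics also notched
    notch_width: float = 1.0  # Hz half-bandwidth of each band-stop
    notch_attenuation_db: float = 53.0

    def __post_init__(self) -> None:
        if self.lowpass_stop <= self.lowpass_cutoff:
            raise ValueError("lowpass_stop must exceed lowpass_cutoff")
        if self.notch_width <= 0 or self.transition <= 0:
            raise ValueError("filter widths must be positive")


@dataclass(frozen=True)
class FilterbankSettings:
    """Log-spaced Morlet filterbank: (fmin, fmax, n bands, cycles m)."""

    fmin: float
    fmax: float
    n_freqs: int
    morlet_m: float

    def __post_init__(self) -> None:
        if not (0 < self.fmin < self.fmax):
            raise ValueError("need 0 < fmin < fmax")
        if self.n_freqs < 2:
            raise ValueError("need at least 2 frequencies")


#: Band-cluster schemes used to collapse narrowband features for the
#: supervised baseline: name -> (low Hz, high Hz), inclusive.
CRITICALITY_CLUSTERS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta-alpha": (5.4, 11.0),
    "beta": (15.0, 30.0),
    "gamma12": (45.0, 225.0),
}

SYNCHRONY_CLUSTERS: dict[str, tuple[float, float]] = {
    "delta-theta": (2.0, 5.4),
    "alpha": (6.1, 13.0),
    "beta": (15.0, 30.0),
    "gamma1": (40.0, 96.0),
    "gamma2": (110.0, 250.0),
    "gamma3": (270.0, 450.0),
}

CRITICALITY_FEATURES = ("dfa", "bis", "fei")
SYNCHRONY_FEATURES = ("evc", "we", "cc", "le")


@dataclass(frozen=True)
class PipelineConfig:
    sampling_rate: float = 1000.0  # Hz
    filter: FilterSettings = field(default_factory=FilterSettings)
    criticality_bank: FilterbankSettings = field(
        default_factory=lambda: FilterbankSettings(2.0, 225.0, 20, 5.0)
    )
    synchrony_bank: FilterbankSettings = field(
        default_factory=lambda: FilterbankSettings(2.0, 450.0, 50, 7.5)
    )
    criticality_clusters: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CRITICALITY_CLUSTERS)
    )
    synchrony_clusters: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SYNCHRONY_CLUSTERS)
    )
    # DFA: log-spaced window sizes between dfa_min_window seconds and
    # a fraction of the segment length.
    dfa_n_windows: int = 16
    dfa_min_window_s: float = 1.0
    dfa_max_window_frac: float = 0.1
    dfa_lrtc_threshold: float = 0.6  # DFA above this => significant LRTCs
    # fE/I windowing
    fei_window_s: float = 5.0
    fei_min_windows: int = 20
    # BiS: points subsampled from the log-envelope before mixture fitting
    bis_max_samples: int = 2000
    # spike detection
    spike_window_s: float = 0.5
    spike_threshold_sd: float = 7.0
    spike_min_consecutive: int = 3
    # latent space / saliency model
    retained_rank: int = 10
    saliency_bins: int = 30
    n_rank_shuffles: int = 10_000
    # sliding-window analysis
    window_s: float = 600.0
    step_s: float = 60.0
    # tensor validation
    tc_rank: int = 20
    n_mantel_surrogates: int = 1000
    n_phase_surrogates: int = 1000

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls()

    @classmethod
    def reduced(cls) -> "PipelineConfig":
        """Desk-scale preset: same pipeline, smaller bands/windows/rates."""
        return cls(
            sampling_rate=128.0,
            filter=FilterSettings(
                lowpass_cutoff=48.0,
                lowpass_stop=60.0,
                transition=12.0,
                notch_base=50.0,
            ),
            criticality_bank=FilterbankSettings(2.0, 32.0, 8, 5.0),
            synchrony_bank=FilterbankSettings(2.0, 40.0, 10, 7.5),
            criticality_clusters={
                "delta": (2.0, 4.0),
                "theta-alpha": (5.4, 11.0),
                "beta": (15.0, 32.0),
            },
            synchrony_clusters={
                "delta-theta": (2.0, 5.4),
                "alpha": (6.1, 13.0),
                "beta-gamma": (15.0, 40.0),
            },
            bis_max_samples=1500,
            n_rank_shuffles=2000,
            window_s=120.0,
            step_s=60.0,
            tc_rank=5,
        )

    @property
    def n_features(self) -> int:
        """Rows of the raw feature matrix X (k)."""
        return len(CRITICALITY_FEATURES) * self.criticality_bank.n_freqs + len(
            SYNCHRONY_FEATURES
        ) * self.synchrony_bank.n_freqs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
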
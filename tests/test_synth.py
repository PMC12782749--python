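"""Synthetic-data generator: planted statistical structure and determinism."""

import numpy as np
import pytest
from scipy.signal import fftconvolve
from scipy.stats import gaussian_kde

from epinet.features_network import plv_matrix
from epinet.preprocess import morlet_wavelet
from epinet.spikes import cohens_d, detect_spiky_windows, spike_density_per_channel
from epinet.synth import (
    ChannelSpec,
    CohortSpec,
    epinet_channel_spec,
    generate_bistable_envelope,
    generate_cohort,
    generate_coupled_channels,
    generate_fgn,
    inject_spikes,
    nonepinet_channel_spec,
)


def dfa_oracle(x: np.ndarray, sizes: np.ndarray) -> float:
    """Independent brute-force DFA: per-window polyfit detrending and a
    log-log regression of the RMS fluctuation."""
    profile = np.cumsum(x - x.mean())
    fl = []
    for s in sizes:
        resid = []
        for i in range(0, len(profile) - s + 1, s):
            seg = profile[i : i + s]
            t = np.arange(s)
            c = np.polyfit(t, seg, 1)
            resid.append(seg - np.polyval(c, t))
        fl.append(np.sqrt(np.mean(np.concatenate(resid) ** 2)))
    return float(np.polyfit(np.log10(sizes), np.log10(fl), 1)[0])


class TestFractionalGaussianNoise:
    sizes = np.unique(np.logspace(np.log10(10), np.log10(6553), 12).astype(int))

    @pytest.mark.parametrize("hurst", [0.5, 0.8])
    def test_dfa_exponent_matches_target(self, hurst):
        x = generate_fgn(hurst, 2**16, seed=11)
        assert abs(dfa_oracle(x, self.sizes) - hurst) < 0.05

    def test_zero_mean_unit_variance(self):
        x = generate_fgn(0.7, 2**14, seed=0)
        assert abs(x.mean()) < 1e-9
        assert abs(x.std() - 1.0) < 1e-9

    def test_deterministic_under_seed(self):
        assert np.array_equal(generate_fgn(0.8, 4096, seed=5), generate_fgn(0.8, 4096, seed=5))

    def test_invalid_hurst_rejected(self):
        with pytest.raises(ValueError):
            generate_fgn(1.2, 1024)
        with pytest.raises(ValueError):
            generate_fgn(0.0, 1024)


class TestBistableEnvelope:
    def test_equal_levels_unimodal(self):
        from epinet.features_local import bistability_index

        env = generate_bistable_envelope(2.0, 2.0, 0.1, 2**15, seed=0, fs=100.0)
        assert bistability_index(env) <= 0.05

    def test_level_ratio_four_is_bimodal(self):
        from epinet.features_local import bistability_index

        env = generate_bistable_envelope(1.0, 4.0, 0.05, 2**16, seed=1, fs=100.0)
        # both states occupied substantially
        occ_high = np.mean(env > 2.5)
        assert 0.2 <= occ_high <= 0.8
        # independent mode-count oracle: KDE of the log-envelope has 2 maxima
        kde = gaussian_kde(np.log(env[::8]), bw_method=0.15)
        grid = np.linspace(np.log(env).min() - 0.5, np.log(env).max() + 0.5, 400)
        dens = kde(grid)
        peaks = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
            & (dens[1:-1] > 0.1 * dens.max())
        )
        assert len(peaks) == 2
        assert bistability_index(env) > 0.2

    def test_deterministic_and_validated(self):
        a = generate_bistable_envelope(1.0, 4.0, 0.1, 1000, seed=3, fs=100.0)
        b = generate_bistable_envelope(1.0, 4.0, 0.1, 1000, seed=3, fs=100.0)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            generate_bistable_envelope(-1.0, 4.0, 0.1, 1000)
        with pytest.raises(ValueError):
            generate_bistable_envelope(1.0, 4.0, 0.0, 1000)


def _band_phases(data, fs, freq=10.0, m=7.5):
    w = morlet_wavelet(freq, m, fs)
    c = fftconvolve(data, w[None, :], mode="same", axes=-1)
    edge = int(np.ceil(m / freq * fs))
    return np.angle(c[:, edge:-edge])


class TestCoupledChannels:
    fs = 128.0

    def test_full_coupling_gives_unit_plv(self):
        spec = ChannelSpec(hurst_exponent=0.7, coupling_group=1, coupling_strength=1.0)
        rec, _ = generate_coupled_channels([spec, spec], 120.0, self.fs, seed=0, noise_level=0.0)
        plv = plv_matrix(_band_phases(rec.data, self.fs))
        # both channels ride the shared driver phase; residual deviation
        # comes only from each channel's own amplitude modulation
        assert plv[0, 1] > 0.99

    def test_zero_coupling_at_chance_level(self):
        spec = ChannelSpec(hurst_exponent=0.7, coupling_group=1, coupling_strength=0.0)
        rec, _ = generate_coupled_channels([spec, spec], 300.0, self.fs, seed=2)
        phases = _band_phases(rec.data, self.fs)
        plv = plv_matrix(phases)[0, 1]
        # Monte-Carlo null for the PLV of independent phase-diffusion pairs
        rng = np.random.default_rng(0)
        null = []
        n = phases.shape[1]
        for _ in range(50):
            # random-walk phases with matched diffusion produce the same
            # effective number of independent phase samples
            d1 = np.cumsum(rng.standard_normal(n)) * 0.05
            d2 = np.cumsum(rng.standard_normal(n)) * 0.05
            null.append(np.abs(np.mean(np.exp(1j * (d1 - d2)))))
        assert plv < np.percentile(null, 99.5) + 0.1

    def test_group_block_structure(self):
        specs = [
            ChannelSpec(hurst_exponent=0.7, coupling_group=g, coupling_strength=0.9)
            for g in (1, 1, 2, 2, 3, 3)
        ]
        rec, _ = generate_coupled_channels(specs, 180.0, self.fs, seed=8)
        plv = plv_matrix(_band_phases(rec.data, self.fs))
        adjacency = np.array([[int(a.coupling_group == b.coupling_group) for b in specs] for a in specs])
        within = plv[(adjacency == 1) & ~np.eye(6, dtype=bool)]
        between = plv[adjacency == 0]
        assert within.min() > 0.8
        assert between.max() < 0.3

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_coupled_channels([], 10.0, self.fs)


class TestSpikeInjection:
    def test_rate_zero_unchanged(self, rng):
        x = rng.standard_normal(10_000)
        y, times = inject_spikes(x, 0.0, 10.0, seed=0, fs=100.0)
        assert np.array_equal(x, y)
        assert times.size == 0

    def test_suprathreshold_spikes_recovered(self, rng):
        fs = 200.0
        x = rng.standard_normal(int(600 * fs))
        y, times = inject_spikes(x, 2.0, 10.0, seed=4, fs=fs)
        assert times.size > 0
        flags = detect_spiky_windows(y, fs)
        hit = sum(flags[min(int(t / 0.5), len(flags) - 1)] for t in times)
        assert hit / times.size >= 0.9

    def test_subthreshold_spikes_invisible(self, rng):
        fs = 200.0
        x = rng.standard_normal(int(120 * fs))
        y, times = inject_spikes(x, 5.0, 1.0, seed=5, fs=fs)
        assert times.size > 0
        assert detect_spiky_windows(y, fs).sum() == 0


class TestCohort:
    def test_label_bookkeeping(self):
        spec = CohortSpec(4, 20, 60.0, 128.0, epinet_fraction=0.25, seed=0)
        recs, gt = generate_cohort(spec)
        assert len(recs) == 4
        for rec in recs:
            assert rec.n_channels == 20
            assert rec.labels.count("EpiNet") == 5
        assert len(gt.labels) == 80

    def test_sleep_ultradian_autocorrelation(self):
        period_min = 10.0
        spec = CohortSpec(1, 4, 3600.0, 64.0, ultradian_period=period_min, seed=3)
        _, gt = generate_cohort(spec, mode="sleep")
        s = gt.saliency["sub-00"][0]  # an EpiNet channel's trace, dt = 1 s
        assert s.min() >= 0.0 and s.max() <= 1.0
        sc = s - s.mean()
        ac = np.correlate(sc, sc, mode="full")[sc.size - 1 :]
        ac /= ac[0]
        lag = np.arange(s.size)
        window = (lag > 300) & (lag < 900)  # search around one period
        peak_lag = lag[window][np.argmax(ac[window])]
        assert abs(peak_lag - period_min * 60) < 120

    def test_bit_identical_under_seed(self):
        spec = CohortSpec(2, 4, 30.0, 128.0, seed=9)
        a, _ = generate_cohort(spec)
        b, _ = generate_cohort(spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.data, rb.data)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(0, 4, 30.0, 128.0)
        with pytest.raises(ValueError):
            ChannelSpec(hurst_exponent=0.4)
        with pytest.raises(ValueError):
            ChannelSpec(coupling_strength=1.5)


@pytest.fixture(scope="module")
def contrast_recording():
    """20 nominal EpiNet + 20 nominal background channels, 10 min."""
    specs = [epinet_channel_spec(group=1) for _ in range(20)]
    specs += [nonepinet_channel_spec(group=2 + i // 4) for i in range(20)]
    rec, _ = generate_coupled_channels(specs, 600.0, 128.0, seed=4242)
    return rec


class TestPlantedContrast:
    """With strongly separated specs every feature family separates groups."""

    def test_feature_families_separate(self, contrast_recording, cfg):
        """Each biomarker family separates the groups (|d| >= 1) in its
        operating frequency cluster; pooling disjoint bands would only
        dilute band-specific effects like bistability."""
        import warnings

        from epinet.features import extract_features
        from epinet.features_local import collapse_bands
        from epinet.preprocess import log_spaced_freqs

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = extract_features(contrast_recording, cfg)
        pos = contrast_recording.positive_mask()
        crit_f = log_spaced_freqs(
            cfg.criticality_bank.fmin, cfg.criticality_bank.fmax,
            cfg.criticality_bank.n_freqs,
        )
        sync_f = log_spaced_freqs(
            cfg.synchrony_bank.fmin, cfg.synchrony_bank.fmax,
            cfg.synchrony_bank.n_freqs,
        )
        for family in ("dfa", "bis", "we"):
            mask = (fm.rows["feature"] == family).to_numpy()
            crit = family in ("dfa", "bis", "fei")
            vals, _ = collapse_bands(
                fm.X[mask].T,
                crit_f if crit else sync_f,
                cfg.criticality_clusters if crit else cfg.synchrony_clusters,
            )
            ds = [
                cohens_d(vals[pos, i], vals[~pos, i]) for i in range(vals.shape[1])
            ]
            best = np.nanmax(np.abs(ds))
            assert best >= 1.0, f"{family}: best cluster |d|={best:.2f} < 1"

    def test_spike_density_separates(self, contrast_recording):
        rec = contrast_recording
        dens = spike_density_per_channel(rec.data, rec.fs)
        labels = rec.positive_mask()
        assert cohens_d(dens[labels], dens[~labels]) >= 1.0
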
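"""Source-connectivity stack: eLORETA localization, atlas aggregation,
Hilbert envelopes and orthogonalized AEC."""

import numpy as np
import pytest

from eegnorm.cohort import EpochedSignals, generate_leadfield
from eegnorm.connectivity import (ConnectivityError, ELORETAConfig,
                                  analytic_band_signal, atlas_aggregate,
                                  aec, bandpass_hilbert_envelope,
                                  connectivity_pipeline, eloreta_weights)
from eegnorm.spectral import BandDefinition

ALPHA = BandDefinition("alpha", 8.0, 13.0)


class TestEloreta:
    def test_exact_point_source_localization(self):
        """Noiseless single-source data localizes exactly (the property
        that gives the method its name), over random sources."""
        lf = generate_leadfield(19, 200, seed=3)
        T = eloreta_weights(lf)
        rng = np.random.default_rng(0)
        for j in rng.integers(0, 200, 20):
            s = T @ lf.gain[:, j]
            assert np.argmax(np.abs(s)) == j

    def test_solution_norm_shrinks_with_lambda(self):
        lf = generate_leadfield(12, 80, seed=4)
        x = lf.gain[:, 7]
        norms = [np.linalg.norm(eloreta_weights(lf, ELORETAConfig(lam=l)) @ x)
                 for l in (0.1, 1.0, 10.0, 100.0)]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_operator_finite(self):
        lf = generate_leadfield(10, 60, seed=5)
        T = eloreta_weights(lf)
        assert T.shape == (60, 10)
        assert np.all(np.isfinite(T))

    def test_rank_deficient_leadfield_rejected(self):
        lf = generate_leadfield(6, 30, seed=6)
        lf.gain[3] = lf.gain[2]  # duplicate row -> rank deficient
        with pytest.raises(ConnectivityError):
            eloreta_weights(lf)


class TestAtlasAggregate:
    def test_single_region_identity(self, rng):
        ts = np.tile(rng.standard_normal(100), (5, 1))
        out = atlas_aggregate(ts, np.zeros(5, int))
        assert np.allclose(out[0], ts[0])

    def test_antiphase_cancellation(self, rng):
        s = rng.standard_normal(100)
        out = atlas_aggregate(np.vstack([s, -s]), np.zeros(2, int))
        assert np.allclose(out, 0.0)

    def test_matches_enumeration_oracle(self, rng):
        ts = rng.standard_normal((30, 50))
        labels = rng.integers(0, 4, 30)
        out = atlas_aggregate(ts, labels)
        for r, reg in enumerate(np.unique(labels)):
            assert np.allclose(out[r], ts[labels == reg].mean(axis=0))


class TestEnvelope:
    def test_constant_tone_envelope(self):
        t = np.arange(4000) / 200.0
        x = 2.5 * np.sin(2 * np.pi * 10.0 * t)
        env, trim = bandpass_hilbert_envelope(x, ALPHA, 200.0)
        core = env[0, trim:-trim]
        assert np.mean(core) == pytest.approx(2.5, rel=0.02)

    def test_tracks_slow_modulation(self):
        t = np.arange(6000) / 200.0
        A = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        x = A * np.sin(2 * np.pi * 10.0 * t)
        env, trim = bandpass_hilbert_envelope(x, ALPHA, 200.0)
        core = slice(trim, -trim)
        r = np.corrcoef(env[0, core], A[core])[0, 1]
        assert r > 0.99

    def test_zero_signal_zero_envelope(self):
        env, _ = bandpass_hilbert_envelope(np.zeros(3000), ALPHA, 200.0)
        assert np.allclose(env, 0.0)

    def test_band_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            bandpass_hilbert_envelope(np.zeros(3000),
                                      BandDefinition("hi", 30.0, 45.0),
                                      80.0)


def _band_noise(rng, n, rate=200.0):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / rate)
    x = np.fft.irfft(spec * ((f >= 8) & (f <= 13)), n)
    return x / x.std()


class TestAEC:
    def test_self_correlation_contracts(self, rng):
        x = _band_noise(rng, 4000)
        ax, trim = analytic_band_signal(x, ALPHA, 200.0)
        assert aec(ax[0], ax[0], orthogonalize=False, trim=trim) == \
            pytest.approx(1.0, abs=1e-12)
        # orthogonalization removes the shared zero-lag component entirely
        assert abs(aec(ax[0], ax[0], orthogonalize=True, trim=trim)) < 0.05

    def test_independent_signals_near_zero(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            x = _band_noise(rng, 200 * 60)
            y = _band_noise(rng, 200 * 60)
            ax, trim = analytic_band_signal(np.vstack([x, y]), ALPHA, 200.0)
            if abs(aec(ax[0], ax[1], trim=trim)) < 0.12:
                hits += 1
        assert hits >= 9

    def test_orthogonalized_aec_scale_invariant(self, rng):
        x = _band_noise(rng, 5000)
        y = _band_noise(rng, 5000)
        ax, trim = analytic_band_signal(np.vstack([x, y]), ALPHA, 200.0)
        a = aec(ax[0], ax[1], trim=trim)
        b = aec(5.0 * ax[0], 0.1 * ax[1], trim=trim)
        assert a == pytest.approx(b, abs=1e-10)

    def test_constant_envelope_plain_mode_errors(self):
        t = np.arange(1000) / 200.0
        x = np.exp(2j * np.pi * 10.0 * t)  # exactly constant envelope
        with pytest.raises(ConnectivityError):
            aec(x, x * np.exp(1j * 0.3), orthogonalize=False)

    def test_mismatched_shapes_raise(self, rng):
        with pytest.raises(ValueError):
            aec(np.zeros(10, complex), np.zeros(11, complex))


class TestPipeline:
    def _setup(self, seed=0):
        lf = generate_leadfield(10, 60, seed=seed)
        labels = np.arange(60) % 6
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((3, 10, 2000))
        ep = EpochedSignals("sub", 200.0, data, lf.channels)
        return ep, lf, labels

    def test_unique_pair_count(self):
        ep, lf, labels = self._setup()
        mats = connectivity_pipeline(ep, lf, labels, [ALPHA])
        C = mats["alpha"]
        assert C.shape == (6, 6)
        iu = np.triu_indices(6, 1)
        assert len(C[iu]) == 6 * 5 // 2
        assert np.allclose(C, C.T, atol=1e-12)
        assert np.all(np.abs(C) <= 1.0)

    def test_epoch_order_invariance(self):
        ep, lf, labels = self._setup(1)
        m1 = connectivity_pipeline(ep, lf, labels, [ALPHA])
        ep2 = EpochedSignals("sub", 200.0, ep.data[::-1].copy(), ep.channels)
        m2 = connectivity_pipeline(ep2, lf, labels, [ALPHA])
        assert np.allclose(m1["alpha"], m2["alpha"], atol=1e-12)

    def test_channel_mismatch_raises(self):
        ep, lf, labels = self._setup(2)
        bad = EpochedSignals("sub", 200.0, ep.data[:, :8], ep.channels[:8])
        with pytest.raises(ConnectivityError):
            connectivity_pipeline(bad, lf, labels, [ALPHA])

    def test_planted_coupled_sources_detected(self):
        """Two sources sharing a slow amplitude envelope on independent
        carriers, embedded among sources with independent alpha activity
        and mixed through the leadfield, should show region-pair AEC above
        the uncoupled 95th percentile in most draws."""
        hits = 0
        seeds = (9, 10, 12)
        for seed in seeds:
            lf = generate_leadfield(19, 24, seed=seed)
            labels = np.arange(24)
            G = lf.gain / np.linalg.norm(lf.gain, axis=0)
            ang = np.abs(G.T @ G)
            np.fill_diagonal(ang, 1.0)
            # plant at the two most spatially distinct sources
            p, q = np.unravel_index(np.argmin(ang), ang.shape)
            rng = np.random.default_rng(seed)
            n = 6000
            src = np.vstack([_band_noise(rng, n) for _ in range(24)])
            slow = np.fft.irfft(
                np.fft.rfft(rng.standard_normal(n))
                * (np.fft.rfftfreq(n, 1 / 200.0) <= 1.0), n)
            env = np.clip(1.0 + 0.8 * slow / slow.std(), 0.0, None)
            src[p] = 1.5 * env * _band_noise(rng, n)
            src[q] = 1.5 * env * _band_noise(rng, n)
            ep = EpochedSignals("sub", 200.0,
                                (lf.gain @ src)[None, :, :], lf.channels)
            C = connectivity_pipeline(ep, lf, labels, [ALPHA])["alpha"]
            iu = np.triu_indices(24, 1)
            planted = tuple(sorted((int(p), int(q))))
            others = [v for pr, v in zip(zip(*iu), C[iu]) if pr != planted]
            hits += C[planted] > np.percentile(others, 95)
        assert hits >= len(seeds) - 1
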
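import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from gradedbci.synthetic import (
    FS_HZ,
    N_CHANNELS,
    SAMPLES_PER_FRAME,
    CueEvent,
    RawSegment,
    inject_artifacts,
    simulate_voltage,
    stim_pulse_times,
)
from gradedbci.preprocess import (
    ARTIFACT_WINDOW_S,
    MWPExtractor,
    choose_sentinels,
    clean_frame,
    detect_artifacts,
    excise,
    level_band_edges,
    wavelet_scale_means,
)


def noise_frame(rng, sd=30.0, n=SAMPLES_PER_FRAME):
    return RawSegment(samples=sd * rng.standard_normal((N_CHANNELS, n)), t0_s=0.0)


class TestBandEdges:
    def test_multiunit_band(self):
        lo, hi = level_band_edges()
        assert int(lo) == 234
        assert lo == pytest.approx(30000 / 2**7)
        assert hi == 1875.0

    @pytest.mark.parametrize("freq,expected_level", [(300, 6), (600, 5), (1400, 4)])
    def test_sine_lands_in_its_dyadic_band(self, freq, expected_level):
        """A mid-band sinusoid has its largest mean |coef| at the level whose
        dyadic band contains it (band edges themselves are leaky for db4)."""
        t = np.arange(SAMPLES_PER_FRAME) / FS_HZ
        sine = np.sin(2 * np.pi * freq * t)[None, :]
        means = wavelet_scale_means(sine)[0]
        assert [4, 5, 6][means.argmax()] == expected_level


class TestDetect:
    def test_clean_frame_no_events(self, rng):
        # 4-of-12 coincidence of |x| > 500 at sigma=30 is astronomically rare
        p1 = 2 * norm.sf(500 / 30)
        window = int(0.0005 * FS_HZ) * 2 + 1
        from scipy.stats import binom
        p_any = 1 - binom.cdf(3, 12, 1 - (1 - p1) ** window)
        assert p_any * SAMPLES_PER_FRAME < 1e-6
        sent = choose_sentinels(0)
        assert len(detect_artifacts(noise_frame(rng), sent)) == 0

    def test_single_transient_detected(self, rng):
        seg = noise_frame(rng)
        seg.samples[:, 1500:1520] += 600.0
        sent = choose_sentinels(0)
        events = detect_artifacts(seg, sent)
        assert len(events) == 1

    def test_below_consensus_not_detected(self, rng):
        seg = noise_frame(rng)
        sent = choose_sentinels(0)
        seg.samples[sent[:3], 1500:1520] += 600.0
        assert len(detect_artifacts(seg, sent)) == 0

    def test_short_frame_rejected(self, rng):
        seg = RawSegment(samples=np.zeros((N_CHANNELS, 50)), t0_s=0.0)
        with pytest.raises(ValueError):
            detect_artifacts(seg, choose_sentinels(0))


class TestExcise:
    def test_no_events_identity(self, rng):
        seg = noise_frame(rng)
        out, frac = excise(seg, [])
        assert frac == 1.0
        assert np.array_equal(out.samples, seg.samples)

    def test_20hz_retains_93_percent(self, rng):
        seg = noise_frame(rng)
        pulses = stim_pulse_times(0.0, 0.1)
        seg = inject_artifacts(seg, pulses, 600.0)
        out, frac, events = clean_frame(seg, choose_sentinels(0))
        assert len(events) == 2
        assert out.n_samples == 2790
        assert frac == pytest.approx(0.93)

    def test_seven_events_capped_at_five(self, rng):
        seg = noise_frame(rng)
        seg = inject_artifacts(seg, np.arange(7) * 0.012, 600.0)
        out, frac, events = clean_frame(seg, choose_sentinels(0))
        assert len(events) == 7
        assert frac == pytest.approx(0.825)

    @settings(derandomize=True, max_examples=30)
    @given(
        pulses=st.lists(
            st.floats(0.0, 0.099, allow_nan=False), min_size=0, max_size=12, unique=True
        ),
        seed=st.integers(0, 1000),
    )
    def test_retained_fraction_floor(self, pulses, seed):
        """Under any artifact load, at least 82.5% of the frame survives."""
        rng = np.random.default_rng(seed)
        seg = noise_frame(rng)
        seg = inject_artifacts(seg, sorted(pulses), 600.0)
        _, frac, _ = clean_frame(seg, choose_sentinels(0))
        assert frac >= 0.825 - 1e-12


class TestMWPExtractor:
    def test_constant_zero_with_training_stats(self, rng):
        """Zero input decodes to the closed-form -mean/sd per channel-scale."""
        frames = [noise_frame(rng) for _ in range(30)]
        ext = MWPExtractor(smooth_frames=1)
        ext.fit(frames)
        zeros = [RawSegment(np.zeros((N_CHANNELS, SAMPLES_PER_FRAME)), t0_s=0.0)]
        z = ext.transform(zeros)
        expected = (-ext.mean_ / ext.std_).mean(axis=1)
        assert np.allclose(z[0], expected)
        assert np.allclose(z[0], z[-1])

    def test_zero_variance_channel_flagged(self):
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(20):
            s = 30.0 * rng.standard_normal((N_CHANNELS, SAMPLES_PER_FRAME))
            s[5] = 0.0  # dead electrode
            frames.append(RawSegment(s, t0_s=0.0))
        ext = MWPExtractor(smooth_frames=1)
        z = ext.fit_transform(frames)
        assert ext.zero_variance_[5].all()
        assert np.all(z[:, 5] == 0.0)

    def test_baseline_subtraction_zero_means_stationary(self, rng):
        """With the 15 s baseline boxcar on, stationary MWP converges to 0."""
        frames = [noise_frame(rng) for _ in range(250)]
        ext = MWPExtractor(baseline_enabled=True)
        z = ext.fit_transform(frames)
        assert abs(z[200:].mean()) < 0.05

    def test_artifact_excision_bias_and_invariance(self, default_profiles):
        """Injecting 20 Hz artifacts and excising them leaves the MWP stream
        nearly unchanged: per-scale bias < 2% and standardized RMS
        difference < 0.35 under default tuning conditions.  (The removed
        7% of wavelet coefficients per frame sets an irreducible sampling
        noise floor for untuned channels.)"""
        from gradedbci.task_design import BlockSpec, VIRTUAL_ANGLES, make_block

        spec = BlockSpec(1, "open_loop", VIRTUAL_ANGLES, 0.0, 11)
        cues = make_block(spec)[:12]  # 60 s
        segs = list(simulate_voltage(cues, default_profiles, seed=5))
        sent = choose_sentinels(0)
        segs_ae = []
        for s in segs:
            pulses = stim_pulse_times(s.t0_s, s.t0_s + 0.1)
            sa = inject_artifacts(s, pulses, 600.0)
            sc, frac, _ = clean_frame(sa, sent)
            assert frac >= 0.825
            segs_ae.append(sc)
        ext = MWPExtractor()
        raw = ext._collect(segs)[0]
        raw_ae = ext._collect(segs_ae)[0]
        rel_bias = np.abs(np.mean((raw_ae - raw) / raw, axis=(0, 1)))
        assert np.all(rel_bias < 0.02)
        z = ext.fit_transform(segs)
        za = ext.transform(segs_ae)
        assert np.sqrt(np.mean((z - za) ** 2)) < 0.35
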
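import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import spearmanr

from gradedbci.task_design import BlockSpec, CueEvent, VIRTUAL_ANGLES, make_block
from gradedbci.synthetic import (
    BAND_HIGH_HZ,
    BAND_LOW_HZ,
    FS_HZ,
    N_CHANNELS,
    OnlineMwpSimulator,
    ChannelTuningProfile,
    assign_profiles,
    inject_artifacts,
    simulate_mwp,
    simulate_voltage,
    stim_pulse_times,
)


class TestAssignProfiles:
    def test_counts(self):
        profs = assign_profiles(56, seed=1)
        assert len(profs) == 96
        assert sum(p.klass != "flat" for p in profs) == 56
        assert sorted(p.channel_id for p in profs) == list(range(1, 97))

    def test_all_flat(self):
        profs = assign_profiles(0, seed=1)
        assert all(p.klass == "flat" and p.gain == 0.0 for p in profs)

    def test_mixture_multinomial(self):
        """Class counts across seeds stay within 3 sigma of the multinomial law."""
        mix = (0.5, 0.25, 0.25)
        n, reps = 56, 200
        counts = np.zeros(3)
        for seed in range(reps):
            profs = assign_profiles(n, seed=seed, mixture=mix)
            for j, k in enumerate(("increasing", "decreasing_nonmonotone", "nonlinear")):
                counts[j] += sum(p.klass == k for p in profs)
        expected = reps * n * np.asarray(mix)
        sd = np.sqrt(reps * n * np.asarray(mix) * (1 - np.asarray(mix)))
        assert np.all(np.abs(counts - expected) < 3 * sd)

    def test_flat_gain_invariant(self):
        with pytest.raises(ValueError):
            ChannelTuningProfile(channel_id=1, klass="flat", gain=1.0)


class TestTuningShapes:
    def test_shapes(self):
        x = np.linspace(0, 1, 11)
        inc = ChannelTuningProfile(1, "increasing", 1.0)
        assert np.all(np.diff(inc.shape(x)) > 0)
        dec = ChannelTuningProfile(2, "decreasing_nonmonotone", 1.0)
        s = dec.shape(x)
        assert s[0] == 0.0  # rest
        assert s[1] > s[0]  # step up from rest
        assert np.all(np.diff(s[1:]) < 0)  # then decreasing
        assert s[-1] > 0
        flat = ChannelTuningProfile(3, "flat", 0.0)
        assert np.all(flat.shape(x) == 0)
        sat = ChannelTuningProfile(4, "nonlinear", 1.0, nonlinear_kind="saturating")
        assert np.all(np.diff(sat.shape(x)) > 0)
        uni = ChannelTuningProfile(5, "nonlinear", 1.0, center=0.5, width=0.25)
        su = uni.shape(x)
        assert su.argmax() == 5  # unimodal peak at the center


class TestSimulateVoltage:
    def test_bit_reproducible(self, one_increasing_profiles):
        cues = [CueEvent(90.0, 0.0, 1.0)]
        a = list(simulate_voltage(cues, one_increasing_profiles, seed=3))
        b = list(simulate_voltage(cues, one_increasing_profiles, seed=3))
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_power_parseval(self, one_increasing_profiles):
        """Total variance = broadband power + tuned band power within 1%."""
        cues = [CueEvent(165.0, 0.0, 10.0)]
        segs = list(
            simulate_voltage(cues, one_increasing_profiles, seed=1, broadband_sd_uv=20.0)
        )
        v = np.concatenate([s.samples[0] for s in segs])
        prof = one_increasing_profiles[0]
        expected = 20.0**2 + prof.band_power(
            np.clip(165.0 / 180.0, 0, 1)
        )
        assert abs(v.var() - expected) / expected < 0.01
        flat = np.concatenate([s.samples[1] for s in segs])
        assert abs(flat.var() - (400.0 + 100.0)) / 500.0 < 0.01

    def test_noiseless_monotone_band_power(self, one_increasing_profiles):
        """With no broadband noise, band power at 165 deg beats 52.5 deg in
        every trial."""
        cues = []
        t = 0.0
        for _ in range(3):
            for a in (52.5, 165.0):
                cues.append(CueEvent(a, t, 2.0))
                t += 2.0
        segs = list(
            simulate_voltage(cues, one_increasing_profiles, seed=2, broadband_sd_uv=0.0)
        )
        # skip the first second of each cue (latency)
        rms = {52.5: [], 165.0: []}
        for c in cues:
            vals = [
                np.sqrt(np.mean(s.samples[0] ** 2))
                for s in segs
                if s.t0_s >= c.onset_s + 1.0 - 1e-9 and s.t0_s < c.offset_s - 1e-9
            ]
            rms[c.target_angle_deg].append(np.mean(vals))
        assert min(rms[165.0]) > max(rms[52.5])

    def test_flat_array_uncorrelated_with_cue(self, flat_profiles):
        spec = BlockSpec(1, "open_loop", VIRTUAL_ANGLES, 0.0, 5)
        cues = make_block(spec)[:12]  # 60 s
        segs = simulate_voltage(cues, flat_profiles, seed=4)
        onsets = np.array([c.onset_s for c in cues])
        angles = np.array([c.target_angle_deg for c in cues])
        bp, cue_angle = [], []
        sos = sps.butter(4, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=FS_HZ, output="sos")
        for s in segs:
            band = sps.sosfilt(sos, s.samples[:8], axis=1)
            bp.append(np.mean(band**2))
            idx = np.searchsorted(onsets, s.t0_s, side="right") - 1
            cue_angle.append(angles[max(idx, 0)])
        r = np.corrcoef(bp, cue_angle)[0, 1]
        assert abs(r) < 0.1

    def test_monotone_mwp_over_block(self, default_profiles):
        """Per-angle band power on an increasing channel is monotone in angle
        (direct bandpass + RMS, independent of the wavelet pipeline)."""
        inc = next(p for p in default_profiles if p.klass == "increasing")
        ch = inc.channel_id - 1
        spec = BlockSpec(1, "open_loop", VIRTUAL_ANGLES, 0.0, 9)
        cues = make_block(spec)
        segs = list(simulate_voltage(cues, default_profiles, seed=6))
        sos = sps.butter(4, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=FS_HZ, output="sos")
        band = sps.sosfilt(sos, np.concatenate([s.samples[ch] for s in segs]))
        t = np.arange(band.size) / FS_HZ
        angles = sorted({c.target_angle_deg for c in cues})
        means = []
        for a in angles:
            mask = np.zeros(band.size, bool)
            for c in cues:
                if c.target_angle_deg == a:
                    mask |= (t >= c.onset_s + 1.0) & (t <= c.offset_s)
            means.append(np.mean(band[mask] ** 2))
        rho = spearmanr(angles, means).statistic
        assert rho == pytest.approx(1.0)


class TestArtifacts:
    def test_no_pulses_unchanged(self, flat_profiles):
        seg = next(iter(simulate_voltage([CueEvent(0.0, 0.0, 0.1)], flat_profiles, seed=0)))
        out = inject_artifacts(seg, [])
        assert np.array_equal(out.samples, seg.samples)

    def test_20hz_gives_two_per_frame(self):
        pulses = stim_pulse_times(0.0, 0.1)
        assert len(pulses) == 2
        # and across a second, 20 pulses
        assert len(stim_pulse_times(0.0, 1.0)) == 20

    def test_amplitude_on_all_channels(self, flat_profiles):
        seg = next(iter(simulate_voltage([CueEvent(0.0, 0.0, 0.1)], flat_profiles, seed=0)))
        out = inject_artifacts(seg, [0.03], amplitude_uv=600.0)
        i0 = int(0.03 * seg.fs_hz)
        window = np.abs(out.samples[:, i0 : i0 + 105])
        assert np.all(window.max(axis=1) >= 600.0 - 100.0)  # peak minus noise


class TestFeatureLevel:
    def test_simulate_mwp_shapes_and_determinism(self, default_profiles, virtual_block_cues):
        t, X = simulate_mwp(virtual_block_cues, default_profiles, seed=3)
        t2, X2 = simulate_mwp(virtual_block_cues, default_profiles, seed=3)
        assert X.shape == (1200, N_CHANNELS)
        assert np.array_equal(X, X2)

    def test_online_matches_tuning_mean(self, default_profiles):
        sim = OnlineMwpSimulator(400, default_profiles, seed=1, noise_sd=1.0)
        F = np.array([sim.step(1.0) for _ in range(400)])[100:]
        inc = next(p for p in default_profiles if p.klass == "increasing")
        mean = F[:, inc.channel_id - 1].mean()
        assert mean == pytest.approx(inc.gain * 1.0, abs=0.15)
        flat = next(p for p in default_profiles if p.klass == "flat")
        assert abs(F[:, flat.channel_id - 1].mean()) < 0.15

    def test_non_contiguous_cues_rejected(self, default_profiles):
        cues = [CueEvent(90.0, 0.0, 5.0), CueEvent(0.0, 6.0, 5.0)]
        with pytest.raises(ValueError):
            simulate_mwp(cues, default_profiles, seed=0)
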
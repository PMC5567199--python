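"""Synthetic 96-channel intracortical signals with graded angle tuning.

No human recordings from the original experiments were released, so this
module stands in for them.  It emulates the one statistical property the
downstream feature (mean wavelet power) is sensitive to: per-channel power
in the multiunit band (≈234-1875 Hz) that is modulated by the cued wrist
angle.  Channels fall into four tuning classes observed on real arrays —
monotonically increasing with angle, stepping up from rest then decreasing
with non-zero angle, non-linear (unimodal or saturating), and flat
(non-responsive).

Two levels of realism are provided:

- :func:`simulate_voltage` — raw 30 kHz voltage streamed in 100 ms frames:
  broadband Gaussian noise plus a band-limited carrier whose instantaneous
  power follows the channel's tuning curve after a response latency.
  Stimulation artifacts can be injected with :func:`inject_artifacts`.
- :func:`simulate_mwp` — the same tuning expressed directly at the feature
  level (standardized MWP units), cheap enough for many-seed decoder and
  closed-loop experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import signal

from .task_design import CueEvent

FS_HZ = 30_000
N_CHANNELS = 96
FRAME_S = 0.1
SAMPLES_PER_FRAME = int(round(FS_HZ * FRAME_S))  # 3000

#: Multiunit band (Hz): dyadic bands of db4 levels 4-6 at 30 kHz.
BAND_LOW_HZ = 30_000 / 2**7   # 234.375
BAND_HIGH_HZ = 30_000 / 2**4  # 1875.0

TUNING_CLASSES = ("increasing", "decreasing_nonmonotone", "nonlinear", "flat")


@dataclass(frozen=True)
class ChannelTuningProfile:
    """Angle tuning of one channel.

    ``gain`` scales the angle-driven modulation (dimensionless multiple of
    ``baseline_power`` for raw voltage; z-units at the feature level).
    ``center``/``width`` parameterize the unimodal non-linear shape.
    """

    channel_id: int
    klass: str
    gain: float
    baseline_power: float = 100.0  # µV² in the multiunit band
    latency_s: float = 0.3
    center: float = 0.5
    width: float = 0.25
    nonlinear_kind: str = "unimodal"  # or "saturating"

    def __post_init__(self) -> None:
        if self.klass not in TUNING_CLASSES:
            raise ValueError(f"unknown tuning class {self.klass!r}")
        if self.klass == "flat" and self.gain != 0.0:
            raise ValueError("flat channels must have gain 0")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")

    def shape(self, x: np.ndarray) -> np.ndarray:
        """Tuning shape on the normalized angle x in [0, 1] (0 = rest).

        Returns values in [0, ~1.2]; the modulated quantity is
        ``gain * shape(x)`` above baseline.
        """
        x = np.asarray(x, dtype=float)
        if self.klass == "flat":
            return np.zeros_like(x)
        if self.klass == "increasing":
            return x
        if self.klass == "decreasing_nonmonotone":
            # step up from rest, then affine decreasing in non-zero angle
            return np.where(x > 0, 1.0 - 0.6 * x, 0.0)
        if self.nonlinear_kind == "saturating":
            return 1.0 - np.exp(-3.0 * x)
        return np.exp(-0.5 * ((x - self.center) / self.width) ** 2) - np.exp(
            -0.5 * (self.center / self.width) ** 2
        )

    def band_power(self, x: np.ndarray) -> np.ndarray:
        """Instantaneous multiunit-band power (µV²) at normalized angle x."""
        return self.baseline_power * (1.0 + self.gain * self.shape(x))


@dataclass(frozen=True)
class RawSegment:
    """One multichannel voltage frame (µV) sampled at 30 kHz.

    ``splices`` are sample indices where non-adjacent data were rejoined
    after artifact excision; downstream wavelet features exclude
    coefficients whose support straddles a splice.
    """

    samples: np.ndarray  # (channels, time)
    t0_s: float
    fs_hz: int = FS_HZ
    splices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


DEFAULT_MIXTURE = (0.4, 0.25, 0.35)  # increasing, decreasing_nonmonotone, nonlinear


def assign_profiles(
    n_informative: int = 56,
    seed: int | np.random.Generator = 0,
    mixture: Sequence[float] = DEFAULT_MIXTURE,
    gain_range: tuple[float, float] = (0.8, 2.0),
    baseline_power: float = 100.0,
    latency_s: float = 0.3,
    latency_jitter_s: float = 0.1,
    nonlinear_kind: str = "unimodal",
) -> list[ChannelTuningProfile]:
    """Draw tuning profiles for all 96 channels.

    ``n_informative`` channels are assigned to the three responsive classes
    with probabilities ``mixture``; the rest are flat.  Which channel ids are
    informative is a seeded draw, as on a real array.  Response latencies are
    drawn per channel from latency_s +/- latency_jitter_s: real channels do
    not respond in lockstep, and the latency spread is what lets per-channel
    inference separate otherwise similarly tuned electrodes.
    """
    if not 0 <= n_informative <= N_CHANNELS:
        raise ValueError("n_informative must be within 0..96")
    rng = np.random.default_rng(seed)
    p = np.asarray(mixture, dtype=float)
    if p.size != 3 or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("mixture must be 3 non-negative weights")
    p = p / p.sum()
    informative = rng.choice(N_CHANNELS, size=n_informative, replace=False)
    klasses = np.full(N_CHANNELS, "flat", dtype=object)
    klasses[informative] = rng.choice(TUNING_CLASSES[:3], size=n_informative, p=p)
    profiles = []
    for ch in range(N_CHANNELS):
        klass = str(klasses[ch])
        flat = klass == "flat"
        profiles.append(
            ChannelTuningProfile(
                channel_id=ch + 1,
                klass=klass,
                gain=0.0 if flat else float(rng.uniform(*gain_range)),
                baseline_power=baseline_power,
                latency_s=float(
                    latency_s + latency_jitter_s * rng.uniform(-1.0, 1.0)
                ),
                center=float(rng.uniform(0.25, 0.75)),
                width=0.25,
                nonlinear_kind=nonlinear_kind,
            )
        )
    return profiles


def _check_contiguous(cues: Sequence[CueEvent]) -> None:
    for a, b in zip(cues, cues[1:]):
        if abs(a.offset_s - b.onset_s) > 1e-9:
            raise ValueError("cues must be contiguous and non-overlapping")


def normalized_cue_angle(
    cues: Sequence[CueEvent], t: np.ndarray, rest_angle_deg: float, max_angle_deg: float
) -> np.ndarray:
    """Normalized cue angle x(t) in [0, 1] (0 at rest) as a step function of time.

    Times before the first cue map to rest; times after the last cue hold the
    last cue's angle.
    """
    onsets = np.array([c.onset_s for c in cues])
    angles = np.array([c.target_angle_deg for c in cues])
    idx = np.searchsorted(onsets, np.asarray(t, dtype=float), side="right") - 1
    a = np.where(idx >= 0, angles[np.clip(idx, 0, None)], rest_angle_deg)
    return np.clip((a - rest_angle_deg) / (max_angle_deg - rest_angle_deg), 0.0, 1.0)


def _band_sos() -> np.ndarray:
    return signal.butter(
        4, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=FS_HZ, output="sos"
    )


def _sos_variance_gain(sos: np.ndarray) -> float:
    """Variance of the filter's output for unit-variance white-noise input."""
    w, h = signal.sosfreqz(sos, worN=8192, fs=FS_HZ)
    return float(np.mean(np.abs(h) ** 2))


def simulate_voltage(
    cues: Sequence[CueEvent],
    profiles: Sequence[ChannelTuningProfile],
    seed: int | np.random.Generator = 0,
    broadband_sd_uv: float = 20.0,
    rest_angle_deg: float = 0.0,
    max_angle_deg: float = 180.0,
) -> Iterator[RawSegment]:
    """Stream raw voltage frames (100 ms, 96 x 3000 samples, µV).

    Each channel is broadband Gaussian noise plus an independent band-limited
    (≈234-1875 Hz) carrier whose instantaneous power follows the channel's
    tuning curve evaluated at the cue angle ``latency_s`` earlier.  With a
    fixed seed the stream is bit-reproducible.
    """
    cues = list(cues)
    if not cues:
        return
    _check_contiguous(cues)
    if len(profiles) != N_CHANNELS:
        raise ValueError("need 96 channel profiles")
    rng = np.random.default_rng(seed)
    sos = _band_sos()
    gain = _sos_variance_gain(sos)
    # independent filter state per channel
    zi0 = signal.sosfilt_zi(sos)
    zi = np.repeat(zi0[:, None, :], N_CHANNELS, axis=1)
    latency = np.array([p.latency_s for p in profiles])
    lat_samples = np.round(latency * FS_HZ).astype(int)
    t_start, t_end = cues[0].onset_s, cues[-1].offset_s
    n_frames = int(round((t_end - t_start) / FRAME_S))
    # precompute the per-sample normalized cue angle once, padded backwards
    # by the largest channel latency
    pad = int(lat_samples.max()) if lat_samples.size else 0
    grid_t = t_start + (np.arange(-pad, n_frames * SAMPLES_PER_FRAME)) / FS_HZ
    x_grid = normalized_cue_angle(cues, grid_t, rest_angle_deg, max_angle_deg)
    # warm up the filter so the carrier is stationary from the first frame
    warm = rng.standard_normal((N_CHANNELS, 2 * SAMPLES_PER_FRAME))
    _, zi = signal.sosfilt(sos, warm, axis=1, zi=zi)
    for k in range(n_frames):
        t0 = t_start + k * FRAME_S
        white = rng.standard_normal((N_CHANNELS, SAMPLES_PER_FRAME))
        carrier, zi = signal.sosfilt(sos, white, axis=1, zi=zi)
        carrier /= np.sqrt(gain)
        # per-channel instantaneous band power at the delayed cue angle;
        # x(t) is piecewise constant, so most frames see a single value per
        # channel (fast path) and only frames straddling a delayed cue edge
        # need per-segment filling
        base = pad + k * SAMPLES_PER_FRAME
        window = x_grid[base - pad : base + SAMPLES_PER_FRAME]
        if window.size == 0 or np.all(window == window[0]):
            x0 = float(window[0]) if window.size else 0.0
            power = np.array([p.band_power(x0) for p in profiles])
            amp = np.sqrt(power)[:, None]
        else:
            amp = np.empty_like(carrier)
            for ch, prof in enumerate(profiles):
                i0 = base - lat_samples[ch]
                xs = x_grid[i0 : i0 + SAMPLES_PER_FRAME]
                edges = np.flatnonzero(np.diff(xs)) + 1
                if edges.size == 0:
                    amp[ch] = np.sqrt(prof.band_power(xs[0]))
                else:
                    bounds = np.concatenate(([0], edges, [SAMPLES_PER_FRAME]))
                    for i0b, i1b in zip(bounds[:-1], bounds[1:]):
                        amp[ch, i0b:i1b] = np.sqrt(prof.band_power(xs[i0b]))
        noise = broadband_sd_uv * rng.standard_normal((N_CHANNELS, SAMPLES_PER_FRAME))
        yield RawSegment(samples=(noise + amp * carrier), t0_s=t0)


def artifact_template(amplitude_uv: float, fs_hz: int = FS_HZ) -> np.ndarray:
    """Biphasic exponentially-decaying transient, support 3 ms, given peak |amplitude|."""
    n = int(round(0.003 * fs_hz))
    t = np.arange(n) / fs_hz
    wave = np.sin(2 * np.pi * t / 0.002) * np.exp(-t / 0.0008)
    return amplitude_uv * wave / np.max(np.abs(wave))


def stim_pulse_times(t0_s: float, t1_s: float, rate_hz: float = 20.0) -> np.ndarray:
    """Stimulation pulse instants on a fixed-rate grid covering [t0, t1)."""
    k0 = int(np.ceil(t0_s * rate_hz - 1e-9))
    k1 = int(np.ceil(t1_s * rate_hz - 1e-9))
    return np.arange(k0, k1) / rate_hz


def inject_artifacts(
    seg: RawSegment, pulse_times: Sequence[float], amplitude_uv: float = 600.0
) -> RawSegment:
    """Add a stimulation transient on all channels at each pulse time."""
    out = seg.samples.copy()
    tpl = artifact_template(amplitude_uv, seg.fs_hz)
    for tp in np.atleast_1d(np.asarray(pulse_times, dtype=float)):
        i0 = int(round((tp - seg.t0_s) * seg.fs_hz))
        if i0 < 0 or i0 >= seg.n_samples:
            raise ValueError(f"pulse time {tp} outside segment")
        i1 = min(i0 + tpl.size, seg.n_samples)
        out[:, i0:i1] += tpl[: i1 - i0]
    return RawSegment(samples=out, t0_s=seg.t0_s, fs_hz=seg.fs_hz)


#: Quantization step of the raw binary dialect (µV per least significant bit).
RAW_LSB_UV = 0.25


def write_raw_stream(segments: Iterable[RawSegment], bin_path, sidecar_path) -> dict:
    """Write a voltage stream as flat int16 binary plus a JSON sidecar.

    The binary holds the full stream channel-major (channel 0's samples,
    then channel 1's, ...) quantized at 0.25 µV/LSB; the sidecar records
    sampling rate, channel count, start time and sample count.  Intended
    for modest stream lengths — the stream is materialized in memory.
    """
    import json as _json
    from pathlib import Path

    segs = list(segments)
    if not segs:
        raise ValueError("empty stream")
    data = np.concatenate([s.samples for s in segs], axis=1)
    quant = np.clip(np.round(data / RAW_LSB_UV), -32768, 32767).astype(np.int16)
    Path(bin_path).write_bytes(quant.tobytes(order="C"))
    meta = {
        "fs_hz": segs[0].fs_hz,
        "n_channels": int(data.shape[0]),
        "n_samples": int(data.shape[1]),
        "t0_s": segs[0].t0_s,
        "lsb_uv": RAW_LSB_UV,
        "layout": "channel-major int16",
    }
    Path(sidecar_path).write_text(_json.dumps(meta, indent=1) + "\n")
    return meta


def read_raw_stream(bin_path, sidecar_path) -> RawSegment:
    """Read a stream written by :func:`write_raw_stream` as one segment."""
    import json as _json
    from pathlib import Path

    meta = _json.loads(Path(sidecar_path).read_text())
    raw = np.frombuffer(Path(bin_path).read_bytes(), dtype=np.int16)
    samples = raw.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return RawSegment(
        samples=samples * meta["lsb_uv"], t0_s=meta["t0_s"], fs_hz=meta["fs_hz"]
    )


def _profile_arrays(profiles: Sequence[ChannelTuningProfile]) -> dict:
    klass = np.array([TUNING_CLASSES.index(p.klass) for p in profiles])
    return {
        "klass": klass,
        "gain": np.array([p.gain for p in profiles]),
        "center": np.array([p.center for p in profiles]),
        "width": np.array([p.width for p in profiles]),
        "saturating": np.array([p.nonlinear_kind == "saturating" for p in profiles]),
        "latency": np.array([p.latency_s for p in profiles]),
    }


def _eval_tuning(arrs: dict, x: np.ndarray) -> np.ndarray:
    """gain * shape(x) for all channels at once; x is per-channel."""
    k = arrs["klass"]
    out = np.zeros_like(x, dtype=float)
    m = k == 0  # increasing
    out[m] = x[m]
    m = k == 1  # decreasing_nonmonotone
    out[m] = np.where(x[m] > 0, 1.0 - 0.6 * x[m], 0.0)
    m = (k == 2) & arrs["saturating"]
    out[m] = 1.0 - np.exp(-3.0 * x[m])
    m = (k == 2) & ~arrs["saturating"]
    c, w = arrs["center"][m], arrs["width"][m]
    out[m] = np.exp(-0.5 * ((x[m] - c) / w) ** 2) - np.exp(-0.5 * (c / w) ** 2)
    return arrs["gain"] * out


class OnlineMwpSimulator:
    """Frame-by-frame feature-level generator for closed-loop sessions.

    Unlike :func:`simulate_mwp`, the normalized intent driving the tuning
    curves is supplied one frame at a time, so it can depend on what the
    subject observes (the decoded needle or the stimulated wrist).  Noise is
    pre-drawn from the seed, making a session reproducible given the same
    intent sequence.
    """

    def __init__(
        self,
        n_frames: int,
        profiles: Sequence[ChannelTuningProfile],
        seed: int | np.random.Generator = 0,
        noise_sd: float = 1.0,
        smooth_frames: int = 10,
        frame_s: float = FRAME_S,
    ):
        if len(profiles) != N_CHANNELS:
            raise ValueError("need 96 channel profiles")
        self.arrs = _profile_arrays(profiles)
        self.lat_frames = np.maximum(
            np.round(self.arrs["latency"] / frame_s).astype(int), 0
        )
        rng = np.random.default_rng(seed)
        self._noise = noise_sd * rng.standard_normal((n_frames, N_CHANNELS))
        self._raw = np.empty((n_frames, N_CHANNELS))
        self._intent = np.zeros(n_frames)
        self.smooth_frames = smooth_frames
        self._k = 0

    def step(self, intent_x: float) -> np.ndarray:
        """Advance one 100 ms frame; returns the 96 smoothed feature values."""
        k = self._k
        if k >= self._noise.shape[0]:
            raise RuntimeError("simulator exhausted")
        self._intent[k] = float(intent_x)
        xi = self._intent[np.maximum(k - self.lat_frames, 0)]
        self._raw[k] = _eval_tuning(self.arrs, xi) + self._noise[k]
        out = self._raw[max(0, k - self.smooth_frames + 1) : k + 1].mean(axis=0)
        self._k = k + 1
        return out


def simulate_mwp(
    cues: Sequence[CueEvent],
    profiles: Sequence[ChannelTuningProfile],
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
    smooth_frames: int = 10,
    rest_angle_deg: float = 0.0,
    max_angle_deg: float = 180.0,
    frame_s: float = FRAME_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-level generator: standardized MWP frames without raw voltage.

    Each channel's per-frame value is ``gain * shape(x(t - latency))`` plus
    white Gaussian noise, then smoothed by the same trailing 1 s boxcar the
    raw pipeline applies.  Returns ``(t, X)`` with ``t`` the frame-end times
    and ``X`` of shape (n_frames, 96) in z-like units.
    """
    cues = list(cues)
    _check_contiguous(cues)
    if len(profiles) != N_CHANNELS:
        raise ValueError("need 96 channel profiles")
    rng = np.random.default_rng(seed)
    t_start, t_end = cues[0].onset_s, cues[-1].offset_s
    n = int(round((t_end - t_start) / frame_s))
    t = t_start + (np.arange(n) + 1) * frame_s  # frame-end times
    t_mid = t - frame_s / 2
    X = np.empty((n, N_CHANNELS))
    for ch, prof in enumerate(profiles):
        x = normalized_cue_angle(cues, t_mid - prof.latency_s, rest_angle_deg, max_angle_deg)
        X[:, ch] = prof.gain * prof.shape(x)
    X += noise_sd * rng.standard_normal(X.shape)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        pad = np.repeat(X[:1], smooth_frames - 1, axis=0)
        X = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="valid"), 0, np.vstack([pad, X])
        )
    return t, X
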
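"""Stimulation-artifact excision and mean-wavelet-power (MWP) features.

Raw 30 kHz voltage is processed in 100 ms frames.  Stimulation artifacts —
large transients common to many channels — are detected by a consensus
rule (|v| > 500 µV simultaneously on at least 4 of 12 fixed sentinel
channels) and a 3.5 ms window around each detection is excised, the
remaining data rejoined.  At most five excisions are honored per frame, so
every frame retains at least 82.5% of its samples.

The MWP feature is then computed per frame and channel: a db4 discrete
wavelet decomposition, the mean absolute detail coefficient at the levels
whose dyadic bands tile the multiunit band (levels 4-6 at 30 kHz,
234.375-1875 Hz), a trailing 1 s boxcar smoother, an optional trailing
15 s boxcar baseline subtraction (used in the imagined/virtual experiment
only), z-standardization per channel and level against training-block
statistics, and finally an average over levels — 96 values per 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pywt
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import FS_HZ, N_CHANNELS, SAMPLES_PER_FRAME, RawSegment

ARTIFACT_THRESHOLD_UV = 500.0
ARTIFACT_CONSENSUS = 4
N_SENTINELS = 12
ARTIFACT_WINDOW_S = 0.0035
COINCIDENCE_TOL_S = 0.0005
MAX_EXCISIONS_PER_FRAME = 5
MIN_VALID_FRACTION = 1.0 - MAX_EXCISIONS_PER_FRAME * ARTIFACT_WINDOW_S / 0.1  # 0.825

DEFAULT_WAVELET = "db4"
#: Decomposition levels retained; level ``k`` covers fs/2^(k+1) .. fs/2^k.
DEFAULT_LEVELS = (4, 5, 6)


@dataclass(frozen=True)
class ArtifactEvent:
    """A detected stimulation artifact and the span excised around it."""

    time_s: float
    excised_start_s: float
    excised_stop_s: float


def level_band_edges(levels: Sequence[int] = DEFAULT_LEVELS, fs_hz: float = FS_HZ) -> tuple[float, float]:
    """Frequency band (Hz) jointly covered by the given dyadic detail levels."""
    lo = fs_hz / 2 ** (max(levels) + 1)
    hi = fs_hz / 2 ** min(levels)
    return lo, hi


def choose_sentinels(seed: int | np.random.Generator = 0, n: int = N_SENTINELS) -> np.ndarray:
    """Randomly select the sentinel channels used for artifact detection.

    Chosen once per session with a fixed seed, mirroring the online system.
    """
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(N_CHANNELS, size=n, replace=False))


def detect_artifacts(
    seg: RawSegment,
    sentinel_channels: Sequence[int],
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
    consensus: int = ARTIFACT_CONSENSUS,
    coincidence_s: float = COINCIDENCE_TOL_S,
    window_s: float = ARTIFACT_WINDOW_S,
) -> list[ArtifactEvent]:
    """Find artifact instants by sentinel-channel threshold consensus.

    An event is declared wherever at least ``consensus`` of the sentinel
    channels exceed ``threshold_uv`` in magnitude within the same
    ``coincidence_s`` tolerance; events closer than ``window_s`` are merged.
    """
    if seg.duration_s < window_s:
        raise ValueError("frame shorter than the excision window")
    sent = np.asarray(sentinel_channels, dtype=int)
    exceed = np.abs(seg.samples[sent]) > threshold_uv
    # tolerate sub-sample misalignment across channels
    tol = max(1, int(round(coincidence_s * seg.fs_hz)))
    exceed = ndimage.maximum_filter1d(exceed.astype(np.uint8), size=2 * tol + 1, axis=1)
    hits = exceed.sum(axis=0) >= consensus
    if not hits.any():
        return []
    # run starts
    starts = np.flatnonzero(np.diff(np.concatenate(([0], hits.view(np.int8)))) == 1)
    merge_gap = int(round(window_s * seg.fs_hz))
    events: list[ArtifactEvent] = []
    last = -merge_gap - 1
    n = seg.n_samples
    w = int(round(window_s * seg.fs_hz))
    # run starts are already `tol` samples early because of the dilation, so
    # the excised span starts at the detection instant and runs forward,
    # covering the transient's tail
    for idx in starts:
        if idx - last < merge_gap:
            continue
        last = idx
        start = int(np.clip(idx, 0, max(0, n - w)))
        events.append(
            ArtifactEvent(
                time_s=seg.t0_s + idx / seg.fs_hz,
                excised_start_s=seg.t0_s + start / seg.fs_hz,
                excised_stop_s=seg.t0_s + (start + w) / seg.fs_hz,
            )
        )
    return events


def excise(
    seg: RawSegment,
    events: Sequence[ArtifactEvent],
    max_excisions: int = MAX_EXCISIONS_PER_FRAME,
) -> tuple[RawSegment, float]:
    """Remove the excision window of each event and rejoin the remainder.

    At most ``max_excisions`` events are honored per frame, which bounds the
    removed data at 17.5 ms per 100 ms frame (retained fraction >= 0.825).
    Returns the shortened segment and the retained fraction relative to a
    nominal full frame.
    """
    nominal = max(seg.n_samples, SAMPLES_PER_FRAME)
    if not events:
        return seg, seg.n_samples / nominal
    keep = np.ones(seg.n_samples, dtype=bool)
    for ev in list(events)[:max_excisions]:
        i0 = int(round((ev.excised_start_s - seg.t0_s) * seg.fs_hz))
        i1 = int(round((ev.excised_stop_s - seg.t0_s) * seg.fs_hz))
        keep[max(0, i0) : max(0, i1)] = False
    # rejoin points in the shortened frame, for splice-aware features
    removed_before = np.cumsum(~keep)
    starts = np.flatnonzero(np.diff(np.concatenate(([1], keep.view(np.int8)))) == -1)
    splices = tuple(
        int(s - removed_before[s - 1]) if s > 0 else 0 for s in starts
    )
    out = RawSegment(
        samples=seg.samples[:, keep], t0_s=seg.t0_s, fs_hz=seg.fs_hz,
        splices=tuple(s for s in splices if 0 < s < int(keep.sum())),
    )
    return out, out.n_samples / nominal


def clean_frame(
    seg: RawSegment, sentinel_channels: Sequence[int], **detect_kwargs
) -> tuple[RawSegment, float, list[ArtifactEvent]]:
    """Detect and excise artifacts in one frame."""
    events = detect_artifacts(seg, sentinel_channels, **detect_kwargs)
    out, frac = excise(seg, events)
    return out, frac, events


def wavelet_scale_means(
    samples: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: Sequence[int] = DEFAULT_LEVELS,
    splices: Sequence[int] = (),
) -> np.ndarray:
    """Mean |detail coefficient| per channel for each retained level.

    ``samples`` is channels x time; returns (channels, len(levels)).  The
    mean of absolute coefficients is a band-power surrogate (raw coefficient
    means cancel to ~0); it is insensitive to moderate frame shortening
    after artifact excision.

    ``splices`` marks sample indices where excised data were rejoined; a
    splice breaks the signal's continuity and transiently inflates detail
    coefficients at the coarse levels, so coefficients whose filter support
    covers a splice are left out of the mean.
    """
    max_level = max(levels)
    coeffs = pywt.wavedec(samples, wavelet, level=max_level, axis=-1)
    # coeffs = [cA_L, cD_L, cD_{L-1}, ..., cD_1]
    # boundary-padding coefficients leak energy in a way that depends on the
    # frame length, which would make the mean drift when excision shortens a
    # frame; trim one filter length of coefficients at each end
    edge = pywt.Wavelet(wavelet).dec_len
    marker_coeffs = None
    if splices:
        # locate the coefficients a splice leaks into by decomposing an
        # impulse marker at the splice positions with the same transform
        marker = np.zeros(samples.shape[-1])
        marker[list(splices)] = 1.0
        marker_coeffs = pywt.wavedec(marker, wavelet, level=max_level)
    out = np.empty((samples.shape[0], len(levels)))
    for j, lev in enumerate(levels):
        c = np.abs(coeffs[max_level - lev + 1])
        valid = np.ones(c.shape[-1], dtype=bool)
        if c.shape[-1] > 2 * edge + 4:
            valid[:edge] = valid[-edge:] = False
        if marker_coeffs is not None:
            m = np.abs(marker_coeffs[max_level - lev + 1])
            valid &= m <= 1e-4 * m.max()
        if valid.sum() >= 4:
            c = c[..., valid]
        out[:, j] = np.mean(c, axis=-1)
    return out


def trailing_boxcar(x: np.ndarray, width: int) -> np.ndarray:
    """Causal boxcar along axis 0 with partial windows during warm-up."""
    if width <= 1:
        return x
    c = np.cumsum(x, axis=0, dtype=float)
    out = np.empty_like(c)
    out[:width] = c[:width] / np.arange(1, width + 1).reshape(-1, *([1] * (x.ndim - 1)))
    out[width:] = (c[width:] - c[:-width]) / width
    return out


def mwp_frames_to_csv(t_s: np.ndarray, mwp: np.ndarray, path) -> None:
    """Write an MWP stream as CSV with columns t_s, ch01..ch96."""
    import pandas as pd

    df = pd.DataFrame(mwp, columns=[f"ch{i + 1:02d}" for i in range(mwp.shape[1])])
    df.insert(0, "t_s", np.asarray(t_s, dtype=float))
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def mwp_frames_from_csv(path) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    return df["t_s"].to_numpy(), df.drop(columns="t_s").to_numpy()


class MWPExtractor(TransformerMixin, BaseEstimator):
    """Mean-wavelet-power transform with training-block standardization.

    ``fit`` consumes the training stream of (possibly excised) frames and
    stores per channel-and-level means and standard deviations of the
    smoothed (and optionally baseline-corrected) scale means; ``transform``
    standardizes a stream against those statistics and averages the levels,
    yielding one row of 96 MWP values per 100 ms frame.

    Parameters
    ----------
    wavelet : mother wavelet name (default "db4").
    levels : decomposition levels to retain; the defaults tile the
        multiunit band 234.375-1875 Hz at 30 kHz.
    smooth_frames : width of the trailing smoothing boxcar (10 = 1 s).
    baseline_frames : width of the trailing baseline boxcar (150 = 15 s).
    baseline_enabled : subtract the slow baseline (virtual experiment only).
    """

    def __init__(
        self,
        wavelet: str = DEFAULT_WAVELET,
        levels: Sequence[int] = DEFAULT_LEVELS,
        smooth_frames: int = 10,
        baseline_frames: int = 150,
        baseline_enabled: bool = False,
    ):
        self.wavelet = wavelet
        self.levels = levels
        self.smooth_frames = smooth_frames
        self.baseline_frames = baseline_frames
        self.baseline_enabled = baseline_enabled

    def _collect(self, frames: Iterable[RawSegment]) -> tuple[np.ndarray, np.ndarray]:
        """One streaming pass: per-frame scale means and frame-end times."""
        vals, times = [], []
        for seg in frames:
            vals.append(
                wavelet_scale_means(seg.samples, self.wavelet, self.levels, seg.splices)
            )
            times.append(seg.t0_s + seg.duration_s)
        if not vals:
            raise ValueError("empty frame stream")
        return np.asarray(vals), np.asarray(times)

    def _process(self, raw: np.ndarray) -> np.ndarray:
        """Smooth and baseline-correct the raw per-frame scale means."""
        sm = trailing_boxcar(raw, self.smooth_frames)
        if self.baseline_enabled:
            sm = sm - trailing_boxcar(sm, self.baseline_frames)
        return sm

    def fit(self, frames: Iterable[RawSegment], y=None) -> "MWPExtractor":
        raw, _ = self._collect(frames)
        proc = self._process(raw)
        self.mean_ = proc.mean(axis=0)
        self.std_ = proc.std(axis=0, ddof=0)
        self.zero_variance_ = self.std_ <= 0
        return self

    def transform(self, frames: Iterable[RawSegment]) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise RuntimeError("MWPExtractor is not fitted")
        raw, times = self._collect(frames)
        z = self._standardize(self._process(raw))
        self.frame_times_ = times
        return z

    def fit_transform(self, frames: Iterable[RawSegment], y=None) -> np.ndarray:
        raw, times = self._collect(frames)
        proc = self._process(raw)
        self.mean_ = proc.mean(axis=0)
        self.std_ = proc.std(axis=0, ddof=0)
        self.zero_variance_ = self.std_ <= 0
        self.frame_times_ = times
        return self._standardize(proc)

    def _standardize(self, proc: np.ndarray) -> np.ndarray:
        std = np.where(self.zero_variance_, 1.0, self.std_)
        z = (proc - self.mean_) / std
        z[:, self.zero_variance_] = 0.0  # flagged degenerate channel-scales
        return z.mean(axis=2)
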
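"""End-to-end simulated sessions: virtual protractor and closed-loop FES.

The runners wire the whole pipeline together at the 10 Hz frame rate every
timing rule in the task is a multiple of:

- :func:`run_virtual` — seven 24-cue blocks of the imagined-control
  experiment.  Block 1 is open-loop (the displayed needle follows the cue);
  blocks 2-7 are decoded online with a beta regression retrained after each
  block on the three most recent blocks.  Afterwards a pooled beta
  regression is fitted to all blocks for per-channel inference, and beta
  and SVR are compared by leave-one-block-out median absolute error.
- :func:`run_fes` — the 11-block closed-loop FES session.  Block 1 is
  cue-driven stimulation, the decoder evolves through block 5 and is then
  frozen, stimulation is recalibrated between blocks 8 and 9, and blocks
  10-11 probe generalization to untrained angles.  Scores, trajectories and
  per-block calibration-difference summaries are emitted.

Synthetic input can be generated at two levels: ``signal_level="mwp"``
(feature-level, the default for session-scale runs) or ``"raw"`` (30 kHz
voltage through artifact excision and the wavelet transform).  A config
plus seed reproduces a session bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluate, plant as plant_mod, preprocess, synthetic, task_design
from .decode import make_decoder, median_abs_error, rolling_training_set, scale_angle, unscale_angle
from .plant import CalibrationMap, StimCommand, WristPlant, recalibrate, sweep_calibration
from .preprocess import MWPExtractor, choose_sentinels, clean_frame
from .synthetic import assign_profiles, inject_artifacts, simulate_mwp, simulate_voltage, stim_pulse_times
from .task_design import BlockSpec, CueEvent, make_block, make_session, make_virtual_session

FRAME_S = synthetic.FRAME_S


@dataclass
class SessionConfig:
    """Fully serializable description of one simulated session."""

    mode: str = "virtual"  # "virtual" | "fes"
    seed: int = 0
    signal_level: str = "mwp"  # "mwp" | "raw"
    # synthetic neural population
    n_informative: int = 56
    mixture: tuple[float, float, float] = synthetic.DEFAULT_MIXTURE
    gain_range: tuple[float, float] = (0.8, 2.0)
    noise_sd: float = 1.0
    latency_s: float = 0.3
    nonlinear_kind: str = "unimodal"
    broadband_sd_uv: float = 20.0
    baseline_power: float = 100.0
    # decoding
    decoder: str | None = None  # default: beta (virtual) / svr (fes)
    svr_c: float = 10.0
    svr_epsilon: float = 0.01
    train_stride: int = 2  # thin SVR training frames for tractable refits
    label_lag_s: float = 0.7  # align training labels with the feature lag
    n_blocks_virtual: int = 7
    # FES plant and stimulation
    fatigue_enabled: bool = True
    inject_stim_artifacts: bool = True  # raw FES mode only
    artifact_amplitude_uv: float = 600.0
    # visual-feedback compensation: the subject leans the imagined force on
    # the observed wrist angle, integrating the error with a leaky gain
    feedback_gain: float = 0.08
    feedback_leak: float = 0.025
    # stimulation amplitude slew filter (per-frame EMA coefficient); FES
    # amplitude updates are ramped rather than stepped
    amplitude_alpha: float = 0.35
    out_dir: str | None = None

    def resolved_decoder(self) -> str:
        if self.decoder is not None:
            return self.decoder
        return "beta" if self.mode == "virtual" else "svr"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        cfg = cls(**d)
        cfg.mixture = tuple(cfg.mixture)
        cfg.gain_range = tuple(cfg.gain_range)
        return cfg


def _child_seed(seed: int, stream: int) -> int:
    """Derive a deterministic sub-seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _angle_domain(mode: str) -> tuple[float, float]:
    if mode == "virtual":
        return task_design.VIRTUAL_REST, 180.0
    return plant_mod.REST_ANGLE_DEG, plant_mod.MAX_ANGLE_DEG


def _cue_angle_at(cues: Sequence[CueEvent], t: np.ndarray) -> np.ndarray:
    onsets = np.array([c.onset_s for c in cues])
    angles = np.array([c.target_angle_deg for c in cues])
    idx = np.clip(np.searchsorted(onsets, np.asarray(t, float), side="right") - 1, 0, None)
    return angles[idx]


def _decoder_digest(model) -> str:
    h = hashlib.sha256()
    if hasattr(model, "coef_"):
        h.update(np.ascontiguousarray(model.coef_).tobytes())
        h.update(np.float64(model.intercept_).tobytes())
        h.update(np.float64(model.phi_).tobytes())
    elif hasattr(model, "svr_"):
        h.update(np.ascontiguousarray(model.svr_.dual_coef_).tobytes())
        h.update(np.ascontiguousarray(model.svr_.support_vectors_).tobytes())
        h.update(np.float64(model.svr_.intercept_[0]).tobytes())
    else:
        h.update(b"passthrough")
    return h.hexdigest()


class _FeatureBank:
    """Per-block neural features with training-set standardization.

    Holds the processed-but-unstandardized stream (smoothed scale means in
    raw mode, feature-level MWP otherwise) so that the z-scoring statistics
    can be recomputed for every rolling training window, exactly as the
    online pipeline recomputes them at each retraining event.
    """

    def __init__(self, per_block: list[np.ndarray], times: list[np.ndarray]):
        self.per_block = per_block
        self.times = times

    def standardizer(self, train_block_idx: Sequence[int]):
        train = np.concatenate([self.per_block[i] for i in train_block_idx], axis=0)
        mean = train.mean(axis=0)
        std = train.std(axis=0, ddof=0)
        zero = std <= 0

        def apply(F: np.ndarray) -> np.ndarray:
            z = (F - mean) / np.where(zero, 1.0, std)
            z[..., zero] = 0.0
            return z.mean(axis=-1) if z.ndim == 3 else z

        return apply


def _generate_features(
    config: SessionConfig,
    blocks: Sequence[BlockSpec],
    profiles,
    rest: float,
    amax: float,
) -> tuple[list[list[CueEvent]], _FeatureBank, list[np.ndarray]]:
    """Build cue lists and the per-block feature bank; returns valid fractions too."""
    cue_lists: list[list[CueEvent]] = []
    t0 = 0.0
    for spec in blocks:
        cues = make_block(spec, t0_s=t0)
        cue_lists.append(cues)
        t0 = cues[-1].offset_s
    feats: list[np.ndarray] = []
    times: list[np.ndarray] = []
    valid_fracs: list[np.ndarray] = []
    if config.signal_level == "mwp":
        for i, cues in enumerate(cue_lists):
            t, X = simulate_mwp(
                cues,
                profiles,
                seed=_child_seed(config.seed, 100 + i),
                noise_sd=config.noise_sd,
                rest_angle_deg=rest,
                max_angle_deg=amax,
            )
            feats.append(X)
            times.append(t)
            valid_fracs.append(np.ones(t.size))
    elif config.signal_level == "raw":
        sentinels = choose_sentinels(_child_seed(config.seed, 7))
        ext = MWPExtractor(baseline_enabled=(config.mode == "virtual"))
        raw_means: list[np.ndarray] = []
        block_sizes: list[int] = []
        all_times: list[float] = []
        for i, cues in enumerate(cue_lists):
            n_before = len(raw_means)
            stream = simulate_voltage(
                cues,
                profiles,
                seed=_child_seed(config.seed, 100 + i),
                broadband_sd_uv=config.broadband_sd_uv,
                rest_angle_deg=rest,
                max_angle_deg=amax,
            )
            vf = []
            for seg in stream:
                if config.mode == "fes" and config.inject_stim_artifacts:
                    pulses = stim_pulse_times(seg.t0_s, seg.t0_s + seg.duration_s)
                    seg = inject_artifacts(seg, pulses, config.artifact_amplitude_uv)
                    seg, frac, _ = clean_frame(seg, sentinels)
                else:
                    frac = 1.0
                raw_means.append(
                    preprocess.wavelet_scale_means(
                        seg.samples, ext.wavelet, ext.levels, seg.splices
                    )
                )
                all_times.append(seg.t0_s + FRAME_S)
                vf.append(frac)
            block_sizes.append(len(raw_means) - n_before)
            valid_fracs.append(np.asarray(vf))
        proc = ext._process(np.asarray(raw_means))
        offs = np.cumsum([0] + block_sizes)
        tarr = np.asarray(all_times)
        for i in range(len(cue_lists)):
            feats.append(proc[offs[i] : offs[i + 1]])
            times.append(tarr[offs[i] : offs[i + 1]])
    else:
        raise ValueError(f"unknown signal_level {config.signal_level!r}")
    return cue_lists, _FeatureBank(feats, times), valid_fracs


def _frame_targets(
    cues: Sequence[CueEvent], t: np.ndarray, rest: float, amax: float,
    lag_s: float = 0.0,
) -> np.ndarray:
    """Scaled cue angle per frame at mid-frame time, optionally lagged.

    Training labels are lagged by the pipeline's known response delay
    (channel latency plus the smoothing boxcar's group delay), so that
    transition frames pair features with the cue that produced them.
    """
    return scale_angle(_cue_angle_at(cues, t - FRAME_S / 2 - lag_s), rest, amax)


@dataclass
class VirtualSessionResult:
    config: SessionConfig
    cue_lists: list
    frame_times: list
    decoded_mu: list  # per block
    decoded_deg: list
    online_mae_deg: float
    pooled_model: object
    p_values: np.ndarray
    n_significant_05: int
    n_significant_01: int
    lobo_mae_beta_deg: float
    lobo_mae_svr_deg: float

    def coefficient_table(self) -> pd.DataFrame:
        m = self.pooled_model
        return pd.DataFrame(
            {
                "channel": np.arange(1, m.coef_.size + 1),
                "coefficient": m.coef_,
                "std_error": m.se_,
                "p_value": m.p_values_,
            }
        )


def run_virtual(config: SessionConfig) -> VirtualSessionResult:
    """Simulate the seven-block imagined graded-control experiment."""
    rest, amax = _angle_domain("virtual")
    blocks = make_virtual_session(config.seed, config.n_blocks_virtual)
    profiles = assign_profiles(
        config.n_informative,
        seed=_child_seed(config.seed, 1),
        mixture=config.mixture,
        gain_range=config.gain_range,
        baseline_power=config.baseline_power,
        latency_s=config.latency_s,
        nonlinear_kind=config.nonlinear_kind,
    )
    cue_lists, bank, _ = _generate_features(config, blocks, profiles, rest, amax)
    n_blocks = len(blocks)
    targets = [
        _frame_targets(cue_lists[i], bank.times[i], rest, amax, config.label_lag_s)
        for i in range(n_blocks)
    ]
    eval_targets = [
        _frame_targets(cue_lists[i], bank.times[i], rest, amax) for i in range(n_blocks)
    ]
    decoded_mu: list[np.ndarray] = []
    abs_err: list[np.ndarray] = []
    for b in range(n_blocks):
        if b == 0:
            mu = eval_targets[0].copy()  # needle pre-programmed to match the cue
        else:
            train_idx = list(range(max(0, b - 3), b))
            std = bank.standardizer(train_idx)
            Xtr, ytr = rolling_training_set(
                [(std(bank.per_block[i]), targets[i]) for i in train_idx]
            )
            model = make_decoder("beta").fit(Xtr, ytr)
            mu = model.predict(std(bank.per_block[b]))
            abs_err.append(
                np.abs(
                    unscale_angle(mu, rest, amax)
                    - unscale_angle(eval_targets[b], rest, amax)
                )
            )
        decoded_mu.append(mu)
    online_mae = float(np.median(np.concatenate(abs_err))) if abs_err else float("nan")
    # offline pooled fit over all blocks for per-channel inference
    std_all = bank.standardizer(list(range(n_blocks)))
    X_all = np.concatenate([std_all(F) for F in bank.per_block], axis=0)
    y_all = np.concatenate(targets)
    pooled = make_decoder("beta").fit(X_all, y_all)
    # beta vs SVR, leave-one-block-out
    err_beta, err_svr = [], []
    for b in range(n_blocks):
        train_idx = [i for i in range(n_blocks) if i != b]
        std = bank.standardizer(train_idx)
        Xtr = np.concatenate([std(bank.per_block[i]) for i in train_idx], axis=0)
        ytr = np.concatenate([targets[i] for i in train_idx])
        Xte = std(bank.per_block[b])
        yte_deg = unscale_angle(eval_targets[b], rest, amax)
        mb = make_decoder("beta").fit(Xtr, ytr)
        err_beta.append(np.abs(unscale_angle(mb.predict(Xte), rest, amax) - yte_deg))
        s = slice(None, None, max(1, config.train_stride))
        ms = make_decoder("svr", C=config.svr_c, epsilon=config.svr_epsilon).fit(Xtr[s], ytr[s])
        err_svr.append(np.abs(unscale_angle(ms.predict(Xte), rest, amax) - yte_deg))
    result = VirtualSessionResult(
        config=config,
        cue_lists=cue_lists,
        frame_times=bank.times,
        decoded_mu=decoded_mu,
        decoded_deg=[unscale_angle(m, rest, amax) for m in decoded_mu],
        online_mae_deg=online_mae,
        pooled_model=pooled,
        p_values=pooled.p_values_,
        n_significant_05=int(np.sum(pooled.p_values_ < 0.05)),
        n_significant_01=int(np.sum(pooled.p_values_ < 0.01)),
        lobo_mae_beta_deg=float(np.median(np.concatenate(err_beta))),
        lobo_mae_svr_deg=float(np.median(np.concatenate(err_svr))),
    )
    if config.out_dir:
        _write_virtual_outputs(result)
    return result


@dataclass
class FesSessionResult:
    config: SessionConfig
    blocks: list
    cue_lists: list
    frame_times: list
    decoded_mu: list
    decoded_deg: list
    achieved_deg: list
    force_lb: list
    fatigue: list
    amplitudes_ma: list
    block_scores: dict
    cdd_by_block: dict
    decoder_digests: dict
    calibration_maps: dict
    angle_force_r: dict
    decoder_: object = None
    standardize_: object = None

    def score_table(self) -> pd.DataFrame:
        desc = {b.block_id: b.purpose for b in self.blocks}
        return evaluate.block_table(self.block_scores, desc)

    def pooled(self, block_ids: Sequence[int]) -> evaluate.BlockScore:
        scores = []
        for bid in block_ids:
            bs = self.block_scores[bid]
            scores.append(bs)
        k = sum(b.total_correct for b in scores)
        n = sum(b.total for b in scores)
        per_angle: dict = {}
        for b in scores:
            for key, (s, t) in b.per_angle.items():
                s0, t0 = per_angle.get(key, (0, 0))
                per_angle[key] = (s0 + s, t0 + t)
        return evaluate.BlockScore(per_angle=per_angle, total_correct=k, total=n)


def _recalibration_history(
    plant: WristPlant, hold_s: float = 1.0, n_levels: int = 7, pause_s: float = 120.0
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude sweep at the muscle's current state, as recalibration input.

    The recalibration break first gives the muscle ``pause_s`` of rest (the
    stimulation is off while the experimenters set up), then sweeps a ladder
    of amplitudes and records the achieved angles.
    """
    rest_cmd = StimCommand(amplitude_ma=0.0)
    for _ in range(int(round(pause_s / plant_mod.UPDATE_PERIOD_S))):
        plant.step(rest_cmd)
    amps, angles = [], []
    for a in np.linspace(0.0, plant_mod.MAX_AMPLITUDE_MA, n_levels):
        cmd = StimCommand(amplitude_ma=float(a))
        for _ in range(int(round(hold_s / plant_mod.UPDATE_PERIOD_S))):
            st = plant.step(cmd)
            amps.append(a)
            angles.append(st.angle_deg)
    return np.asarray(amps), np.asarray(angles)


def run_fes(config: SessionConfig) -> FesSessionResult:
    """Simulate the 11-block closed-loop BCI-FES session.

    At the feature level the loop is closed twice: the decoder output drives
    the stimulation that moves the wrist, and the subject's imagined force
    leans on the observed wrist angle (leaky integral compensation of the
    visual error), as a participant watching their own hand would.  In raw
    signal mode the neural stream is cue-driven (open loop) and the full
    artifact-injection/excision/wavelet pipeline is exercised instead.
    """
    rest, amax = _angle_domain("fes")
    blocks = make_session(config.seed)
    profiles = assign_profiles(
        config.n_informative,
        seed=_child_seed(config.seed, 1),
        mixture=config.mixture,
        gain_range=config.gain_range,
        baseline_power=config.baseline_power,
        latency_s=config.latency_s,
        nonlinear_kind=config.nonlinear_kind,
    )
    n_blocks = len(blocks)
    closed_loop = config.signal_level == "mwp"
    if closed_loop:
        cue_lists = []
        t0 = 0.0
        for spec in blocks:
            cues = make_block(spec, t0_s=t0)
            cue_lists.append(cues)
            t0 = cues[-1].offset_s
        frames_per_block = int(round(120.0 / FRAME_S))
        times = [
            cl[0].onset_s + (np.arange(frames_per_block) + 1) * FRAME_S
            for cl in cue_lists
        ]
        sim = synthetic.OnlineMwpSimulator(
            n_blocks * frames_per_block,
            profiles,
            seed=_child_seed(config.seed, 100),
            noise_sd=config.noise_sd,
        )
        feats_blocks: list[np.ndarray] = []
    else:
        cue_lists, bank, _ = _generate_features(config, blocks, profiles, rest, amax)
        times = bank.times
        feats_blocks = bank.per_block
    targets = [
        _frame_targets(cue_lists[i], times[i], rest, amax, config.label_lag_s)
        for i in range(n_blocks)
    ]
    cue_mu = [
        _frame_targets(cue_lists[i], times[i], rest, amax) for i in range(n_blocks)
    ]
    wplant = WristPlant(
        seed=_child_seed(config.seed, 3), fatigue_enabled=config.fatigue_enabled
    )
    cal = sweep_calibration(wplant)
    calibration_maps = {1: cal}
    algo = config.resolved_decoder()
    model = None
    apply_std = None
    frozen_after = 5
    stride = max(1, config.train_stride)
    decoded_mu: list[np.ndarray] = []
    achieved: list[np.ndarray] = []
    forces: list[np.ndarray] = []
    fatigues: list[np.ndarray] = []
    amps: list[np.ndarray] = []
    digests: dict[int, str] = {}
    block_scores: dict[int, evaluate.BlockScore] = {}
    cdd_by_block: dict[int, evaluate.CddSummary] = {}
    afr: dict[int, float] = {}
    span = amax - rest
    for b in range(n_blocks):
        bid = blocks[b].block_id
        t = times[b]
        # retrain before blocks 2..6 on the <=3 most recent completed blocks;
        # the block-6 model (trained on blocks 3-5) is the frozen decoder for
        # the rest of the session
        if bid > 1 and (model is None or bid <= frozen_after + 1):
            train_idx = list(range(max(0, b - 3), b))
            std = _FeatureBank(feats_blocks, times).standardizer(train_idx)
            Xtr, ytr = rolling_training_set(
                [(std(feats_blocks[i]), targets[i]) for i in train_idx]
            )
            if algo == "svr":
                model = make_decoder(
                    "svr", C=config.svr_c, epsilon=config.svr_epsilon
                ).fit(Xtr[::stride], ytr[::stride])
            else:
                model = make_decoder("beta").fit(Xtr, ytr)
            apply_std = std
        digests[bid] = _decoder_digest(model) if model is not None else "cue-driven"
        # recalibration between blocks 8 and 9: a fresh amplitude sweep at
        # the muscle's current fatigue level, inverted into a new map
        if bid == 9:
            cal = recalibrate(*_recalibration_history(wplant))
            calibration_maps[9] = cal
        traj_t = np.concatenate([[t[0] - FRAME_S], t])
        traj_a = np.empty(traj_t.size)
        traj_f = np.empty(traj_t.size)
        traj_fat = np.empty(traj_t.size)
        traj_a[0] = wplant.state.angle_deg
        traj_f[0] = wplant.state.force_lb
        traj_fat[0] = wplant.state.fatigue
        if closed_loop:
            onsets = np.array([c.onset_s for c in cue_lists[b]])
            x_cue = np.clip(
                (_cue_angle_at(cue_lists[b], t - FRAME_S / 2) - rest) / span, 0, 1
            )
            F = np.empty((t.size, synthetic.N_CHANNELS))
            mu = np.empty(t.size)
            amplitude = np.empty(t.size)
            fb = 0.0
            amp_state = 0.0
            x_obs = (traj_a[0] - rest) / span
            cue_idx_prev = -1
            for k in range(t.size):
                cue_idx = int(
                    np.clip(
                        np.searchsorted(onsets, t[k] - FRAME_S / 2, side="right") - 1,
                        0,
                        None,
                    )
                )
                if cue_idx != cue_idx_prev:
                    fb = 0.0  # re-aim at each new target
                    cue_idx_prev = cue_idx
                use_fb = bid > 1 and config.feedback_gain > 0
                intent = np.clip(x_cue[k] + fb, 0.0, 1.15) if use_fb else x_cue[k]
                F[k] = sim.step(intent)
                if bid == 1:
                    mu[k] = cue_mu[b][k]  # stimulation follows the cue
                else:
                    mu[k] = model.predict_one(apply_std(F[k][None, :])[0])
                a_cmd = cal.amplitude(mu[k])
                amp_state += config.amplitude_alpha * (a_cmd - amp_state)
                amplitude[k] = amp_state
                st = wplant.step(StimCommand(amplitude_ma=float(amplitude[k])))
                traj_a[k + 1] = st.angle_deg
                traj_f[k + 1] = st.force_lb
                traj_fat[k + 1] = st.fatigue
                x_obs = np.clip((st.angle_deg - rest) / span, 0.0, 1.0)
                fb = (1.0 - config.feedback_leak) * fb + config.feedback_gain * (
                    x_cue[k] - x_obs
                )
            feats_blocks.append(F)
        else:
            if bid == 1:
                mu = cue_mu[0].copy()
            else:
                mu = model.predict(apply_std(feats_blocks[b]))
            amplitude = np.asarray(cal.amplitude(mu), dtype=float)
            for k in range(t.size):
                st = wplant.step(StimCommand(amplitude_ma=float(amplitude[k])))
                traj_a[k + 1] = st.angle_deg
                traj_f[k + 1] = st.force_lb
                traj_fat[k + 1] = st.fatigue
        decoded_mu.append(mu)
        achieved.append(traj_a[1:])
        forces.append(traj_f[1:])
        fatigues.append(traj_fat[1:])
        amps.append(amplitude)
        scores = evaluate.score_block(traj_t, traj_a, cue_lists[b])
        block_scores[bid] = evaluate.aggregate(scores)
        cdd_by_block[bid] = evaluate.cdd(
            t, unscale_angle(mu, rest, amax), traj_a[1:], cue_lists[b]
        )
        move = traj_a[1:] > rest + 1.0
        if move.sum() > 10:
            afr[bid] = evaluate.angle_force_correlation(
                traj_a[1:][move], forces[-1][move]
            )
    result = FesSessionResult(
        config=config,
        blocks=blocks,
        cue_lists=cue_lists,
        frame_times=times,
        decoded_mu=decoded_mu,
        decoded_deg=[unscale_angle(m, rest, amax) for m in decoded_mu],
        achieved_deg=achieved,
        force_lb=forces,
        fatigue=fatigues,
        amplitudes_ma=amps,
        block_scores=block_scores,
        cdd_by_block=cdd_by_block,
        decoder_digests=digests,
        calibration_maps=calibration_maps,
        angle_force_r=afr,
        decoder_=model,
        standardize_=apply_std,
    )
    if config.out_dir:
        _write_fes_outputs(result)
    return result


def _frame_df(result, extra: dict[str, list[np.ndarray]]) -> pd.DataFrame:
    rows = {"t_s": np.concatenate(result.frame_times)}
    rows["block"] = np.concatenate(
        [np.full(t.size, i + 1) for i, t in enumerate(result.frame_times)]
    )
    for name, series in extra.items():
        rows[name] = np.concatenate(series)
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def _write_virtual_outputs(result: VirtualSessionResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(result.config.to_json() + "\n")
    _write_csv(
        _frame_df(result, {"decoded_deg": result.decoded_deg}), out / "decoded.csv"
    )
    _write_csv(result.coefficient_table(), out / "beta_coefficients.csv")
    summary = {
        "online_median_abs_error_deg": result.online_mae_deg,
        "lobo_mae_beta_deg": result.lobo_mae_beta_deg,
        "lobo_mae_svr_deg": result.lobo_mae_svr_deg,
        "n_significant_p05": result.n_significant_05,
        "n_significant_p01": result.n_significant_01,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")


def _write_fes_outputs(result: FesSessionResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(result.config.to_json() + "\n")
    _write_csv(
        _frame_df(
            result,
            {
                "decoded_deg": result.decoded_deg,
                "achieved_deg": result.achieved_deg,
                "force_lb": result.force_lb,
                "amplitude_ma": result.amplitudes_ma,
                "fatigue": result.fatigue,
            },
        ),
        out / "trajectory.csv",
    )
    _write_csv(result.score_table(), out / "scores.csv")
    summary = {
        "training_pool_3_5": _pool_summary(result, [3, 4, 5]),
        "test_pre_recal_6_8": _pool_summary(result, [6, 7, 8]),
        "test_post_recal_9_11": _pool_summary(result, [9, 10, 11]),
        "generalization_10_11": _pool_summary(result, [10, 11]),
        "cdd_iqr_by_block": {
            str(k): round(v.iqr_deg, 3) for k, v in result.cdd_by_block.items()
        },
        "decoder_digests": result.decoder_digests,
        "angle_force_r": {str(k): round(v, 4) for k, v in result.angle_force_r.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")


def _pool_summary(result: FesSessionResult, block_ids) -> dict:
    bs = result.pooled(block_ids)
    return {
        "total_correct": bs.total_correct,
        "total": bs.total,
        "accuracy_pct": round(bs.accuracy_pct, 1),
        "se_pct": round(bs.se_pct, 1),
    }


def run_session(config: SessionConfig):
    if config.mode == "virtual":
        return run_virtual(config)
    if config.mode == "fes":
        return run_fes(config)
    raise ValueError(f"unknown mode {config.mode!r}")
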
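"""Stimulation encoding and a simulated wrist plant with fatigue.

The decoder's normalized force command F in [0, 1] is translated into a
stimulation amplitude through a piecewise-linear calibration map and
delivered as current-controlled monophasic pulses (20 Hz, 500 µs, 0-20 mA,
updated every 100 ms).  The plant stands in for the participant's forearm,
the elastic band and the load cell: stimulation recruits wrist flexion
through a monotone saturating curve, the wrist angle relaxes toward the
recruited target with a 0.3 s time constant over the physical range
36° (rest) to 128° (maximal flexion), and the elastic band produces a load
of 0.3-0.7 lb across that range.

Muscle fatigue is a charge-integrating leaky accumulator: sustained
stimulation reduces the effective amplitude, so a calibration map fitted
when the muscle was fresh progressively under-shoots high angles — the
mechanism that inflates the calibration difference distribution (CDD)
across test blocks until the stimulation is recalibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

REST_ANGLE_DEG = 36.0
MAX_ANGLE_DEG = 128.0
ANGLE_RANGE_DEG = MAX_ANGLE_DEG - REST_ANGLE_DEG  # 92
MAX_AMPLITUDE_MA = 20.0
PULSE_RATE_HZ = 20.0
PULSE_WIDTH_US = 500.0
UPDATE_PERIOD_S = 0.1

FORCE_MIN_LB = 0.3
FORCE_MAX_LB = 0.7


@dataclass(frozen=True)
class StimCommand:
    """Stimulation parameters for one 100 ms update."""

    amplitude_ma: float
    pulse_rate_hz: float = PULSE_RATE_HZ
    pulse_width_us: float = PULSE_WIDTH_US
    update_period_s: float = UPDATE_PERIOD_S

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_ma <= MAX_AMPLITUDE_MA:
            raise ValueError("amplitude outside [0, 20] mA")


@dataclass(frozen=True)
class CalibrationMap:
    """Monotone piecewise-linear map from normalized force F to amplitude (mA)."""

    anchors: tuple[tuple[float, float], ...]  # (force_f, amplitude_ma)

    def __post_init__(self) -> None:
        f = np.array([a[0] for a in self.anchors])
        amp = np.array([a[1] for a in self.anchors])
        if f[0] != 0.0 or f[-1] != 1.0:
            raise ValueError("anchors must cover force_f in {0, 1}")
        if np.any(np.diff(f) <= 0) or np.any(np.diff(amp) < 0):
            raise ValueError("anchors must be monotone in force and amplitude")
        if np.any(amp < 0) or np.any(amp > MAX_AMPLITUDE_MA):
            raise ValueError("anchor amplitudes outside [0, 20] mA")

    def amplitude(self, force_f) -> np.ndarray | float:
        f = np.clip(np.asarray(force_f, dtype=float), 0.0, 1.0)
        fx = np.array([a[0] for a in self.anchors])
        ax = np.array([a[1] for a in self.anchors])
        out = np.clip(np.interp(f, fx, ax), 0.0, MAX_AMPLITUDE_MA)
        return float(out) if np.isscalar(force_f) else out


def encode_stim(force_f: float, cal: CalibrationMap) -> StimCommand:
    """Translate a decoded force command into the next stimulation update."""
    return StimCommand(amplitude_ma=float(cal.amplitude(force_f)))


@dataclass(frozen=True)
class PlantState:
    """Wrist angle (deg), load-cell force (lb) and fatigue level in [0, 1]."""

    angle_deg: float = REST_ANGLE_DEG
    force_lb: float = 0.0
    fatigue: float = 0.0


@dataclass
class WristPlant:
    """First-order wrist dynamics driven by stimulation amplitude.

    Parameters
    ----------
    recruit_thresh_ma : motor threshold — amplitudes below it evoke no
        contraction, so the wrist returns fully to rest between cues.
    recruit_tau_ma : curvature of the saturating recruitment curve.
    recruit_sat_ma : amplitude that recruits full flexion when fresh.
    tau_s : mechanical time constant of the wrist (s).
    fatigue_rate : fatigue accumulated per second at full amplitude.
    fatigue_recovery : fractional fatigue recovery per second at rest.
    fatigue_onset, fatigue_gain, fatigue_loss_max : the suprathreshold
        drive is scaled by ``1 - min(loss_max, gain * max(0, fatigue -
        onset))``; accumulated fatigue is functionally silent until it
        crosses the onset, after which the decline is steep — matching the
        abrupt mid-session performance drop seen in FES use — and bounded by
        the fatigue-resistant fiber fraction.
    force_noise_lb : load-cell noise standard deviation (lb).
    """

    recruit_thresh_ma: float = 2.0
    recruit_tau_ma: float = 5.0
    recruit_sat_ma: float = 14.0
    tau_s: float = 0.3
    fatigue_rate: float = 0.0046
    fatigue_recovery: float = 0.0016
    fatigue_onset: float = 0.30
    fatigue_gain: float = 6.0
    fatigue_loss_max: float = 0.6
    fatigue_enabled: bool = True
    force_noise_lb: float = 0.02
    seed: int | np.random.Generator = 0
    state: PlantState = field(default_factory=PlantState)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def recruitment(self, amplitude_ma) -> np.ndarray | float:
        """Normalized recruited flexion g(a) in [0, 1]; monotone saturating
        above the motor threshold, zero below it."""
        a = np.clip(np.asarray(amplitude_ma, dtype=float), 0.0, MAX_AMPLITUDE_MA)
        span = self.recruit_sat_ma - self.recruit_thresh_ma
        rel = np.clip(a - self.recruit_thresh_ma, 0.0, None)
        g = (1.0 - np.exp(-rel / self.recruit_tau_ma)) / (
            1.0 - np.exp(-span / self.recruit_tau_ma)
        )
        out = np.clip(g, 0.0, 1.0)
        return float(out) if np.isscalar(amplitude_ma) else out

    def inverse_recruitment(self, g) -> np.ndarray | float:
        """Amplitude (mA) recruiting normalized flexion g when fresh."""
        g = np.asarray(g, dtype=float)
        span = self.recruit_sat_ma - self.recruit_thresh_ma
        denom = 1.0 - np.exp(-span / self.recruit_tau_ma)
        gc = np.clip(g, 0.0, 1.0)
        a = self.recruit_thresh_ma - self.recruit_tau_ma * np.log1p(
            -np.clip(gc * denom, 0.0, 1.0 - 1e-12)
        )
        a = np.where(gc <= 0, 0.0, a)
        out = np.clip(a, 0.0, MAX_AMPLITUDE_MA)
        return float(out) if np.isscalar(g) else out

    def step(self, cmd: StimCommand, dt: float = UPDATE_PERIOD_S) -> PlantState:
        """Advance the plant by one stimulation update."""
        s = self.state
        loss = min(
            self.fatigue_loss_max,
            self.fatigue_gain * max(0.0, s.fatigue - self.fatigue_onset),
        )
        # fatigue scales the suprathreshold drive; the motor threshold itself
        # does not move
        a_eff = cmd.amplitude_ma
        if a_eff > self.recruit_thresh_ma:
            a_eff = self.recruit_thresh_ma + (a_eff - self.recruit_thresh_ma) * (1.0 - loss)
        target = REST_ANGLE_DEG + ANGLE_RANGE_DEG * self.recruitment(a_eff)
        alpha = 1.0 - np.exp(-dt / self.tau_s)
        angle = s.angle_deg + alpha * (target - s.angle_deg)
        if self.fatigue_enabled:
            # charge-integrating accumulator driven by the commanded current
            dfat = dt * (
                self.fatigue_rate * (cmd.amplitude_ma / MAX_AMPLITUDE_MA)
                - self.fatigue_recovery * s.fatigue
            )
            fatigue = float(np.clip(s.fatigue + dfat, 0.0, 1.0))
        else:
            fatigue = 0.0
        if angle <= REST_ANGLE_DEG + 0.5:
            force = 0.0  # elastic band slack at rest
        else:
            force = (
                FORCE_MIN_LB
                + (FORCE_MAX_LB - FORCE_MIN_LB) * (angle - REST_ANGLE_DEG) / ANGLE_RANGE_DEG
                + self.force_noise_lb * self._rng.standard_normal()
            )
            force = max(force, 0.0)
        self.state = PlantState(angle_deg=float(angle), force_lb=float(force), fatigue=fatigue)
        return self.state

    def reset(self, state: PlantState | None = None) -> None:
        self.state = state if state is not None else PlantState()


def sweep_calibration(plant: WristPlant, n_anchors: int = 5, hold_s: float = 2.0) -> CalibrationMap:
    """Session-start calibration: sweep amplitudes, record achieved angles.

    Holds each of ``n_anchors`` amplitudes from rest for ``hold_s`` and maps
    the achieved normalized flexion back to the amplitude, producing a
    monotone anchor set covering force 0 to 1.  Fatigue accumulated during
    the brief sweep is negligible by construction.
    """
    saved = plant.state
    amps = np.linspace(0.0, plant.recruit_sat_ma, n_anchors)
    achieved = []
    for a in amps:
        plant.reset(replace(saved, angle_deg=REST_ANGLE_DEG))
        cmd = StimCommand(amplitude_ma=float(a))
        for _ in range(int(round(hold_s / UPDATE_PERIOD_S))):
            st = plant.step(cmd)
        achieved.append((st.angle_deg - REST_ANGLE_DEG) / ANGLE_RANGE_DEG)
    plant.reset(saved)
    f = np.clip(np.maximum.accumulate(achieved), 0.0, 1.0)
    f[0], f[-1] = 0.0, 1.0
    # invert achieved(f) -> amplitude at evenly spaced force anchors
    targets = np.linspace(0.0, 1.0, n_anchors)
    anchor_amps = np.interp(targets, f, amps)
    anchor_amps = np.maximum.accumulate(np.clip(anchor_amps, 0.0, MAX_AMPLITUDE_MA))
    return CalibrationMap(anchors=tuple(zip(targets.tolist(), anchor_amps.tolist())))


def recalibrate(
    amplitudes_ma: Sequence[float],
    achieved_angles_deg: Sequence[float],
    n_anchors: int = 5,
    min_samples: int = 50,
) -> CalibrationMap:
    """Refit the calibration map from recent (amplitude, achieved angle) history.

    Bins the commanded amplitudes, takes the median achieved normalized
    flexion per bin, enforces monotonicity, and inverts the relation at
    evenly spaced force anchors, so that at the muscle's current fatigue
    level the decoded force maps to the achieved angle with zero median
    error.  Amplitudes are capped at 20 mA, so flexion lost to extreme
    fatigue beyond the cap cannot be recovered.
    """
    a = np.asarray(amplitudes_ma, dtype=float)
    ang = np.asarray(achieved_angles_deg, dtype=float)
    if a.size != ang.size or a.size < min_samples:
        raise ValueError(f"need at least {min_samples} aligned history samples")
    g = np.clip((ang - REST_ANGLE_DEG) / ANGLE_RANGE_DEG, 0.0, 1.0)
    edges = np.linspace(0.0, MAX_AMPLITUDE_MA, 21)
    mids, med = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (a >= lo) & (a < hi)
        if m.sum() >= 3:
            mids.append(0.5 * (lo + hi))
            med.append(np.median(g[m]))
    if len(mids) < 2:
        raise ValueError("history does not span enough amplitude levels")
    mids = np.asarray(mids)
    med = np.maximum.accumulate(np.asarray(med))
    # collapse plateaus (e.g. the sub-threshold dead zone) so the inversion
    # is well defined
    keep = np.concatenate([[True], np.diff(med) > 1e-9])
    mids, med = mids[keep], med[keep]
    # extrapolate linearly to the cap from the top observed bins
    if med[-1] < 1.0:
        slope = (med[-1] - med[0]) / max(mids[-1] - mids[0], 1e-9)
        top_amp = mids[-1] + (1.0 - med[-1]) / max(slope, 1e-6)
        mids = np.append(mids, min(top_amp, MAX_AMPLITUDE_MA))
        med = np.append(med, 1.0)
    f0, g0 = (0.0, 0.0) if med[0] > 0 else (None, None)
    if f0 is not None:
        mids = np.concatenate([[0.0], mids])
        med = np.concatenate([[0.0], med])
    targets = np.linspace(0.0, 1.0, n_anchors)
    anchor_amps = np.interp(targets, med, mids)
    anchor_amps = np.maximum.accumulate(np.clip(anchor_amps, 0.0, MAX_AMPLITUDE_MA))
    anchor_amps[0] = 0.0
    return CalibrationMap(anchors=tuple(zip(targets.tolist(), anchor_amps.tolist())))
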
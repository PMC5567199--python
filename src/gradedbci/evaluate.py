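"""Scoring of trajectories against cues and the summary statistics.

A cue is scored a success when the trajectory stays within 15° of the
target continuously for at least 2 s inside the scoring window: each
movement cue gets a 6.5 s window (5 s cue plus a 1.5 s grace period for
reaction and system lag), while each rest cue gets a 3.5 s window (its 5 s
minus the preceding cue's grace period).  Dwell time is measured on the
linearly interpolated trajectory, so threshold crossings between samples
count partially and briefly sweeping through the band earns no credit.

Block accuracies are pooled counts k/n with the binomial standard error
100*sqrt(p(1-p)/n).  The calibration difference distribution (CDD) is the
pointwise decoded-minus-achieved angle during movement windows, summarized
per block by its median and interquartile range.  Channel-level condition
contrasts use a two-sided permutation test on the difference of
trial-mean MWP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .task_design import CueEvent

TOLERANCE_DEG = 15.0
DWELL_S = 2.0
GRACE_S = 1.5
MOVE_WINDOW_S = 6.5
REST_WINDOW_S = 3.5
MAX_GAP_S = 0.2


@dataclass(frozen=True)
class CueScore:
    cue: CueEvent
    success: bool
    max_dwell_s: float
    window_bounds_s: tuple[float, float]


@dataclass(frozen=True)
class BlockScore:
    """Pooled success counts with per-angle breakdown and binomial SE."""

    per_angle: dict
    total_correct: int
    total: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.total_correct / self.total

    @property
    def se_pct(self) -> float:
        p = self.total_correct / self.total
        return 100.0 * float(np.sqrt(p * (1.0 - p) / self.total))


@dataclass(frozen=True)
class CddSummary:
    median_deg: float
    iqr_deg: float
    n: int


def max_dwell_in_band(
    t: np.ndarray, angle: np.ndarray, target: float, tol: float = TOLERANCE_DEG
) -> float:
    """Longest continuous time |angle - target| <= tol on the interpolated path."""
    t = np.asarray(t, dtype=float)
    a = np.asarray(angle, dtype=float)
    d = np.abs(a - target) - tol  # inside band where d <= 0
    best = 0.0
    run = 0.0
    entered_at = None
    for i in range(t.size - 1):
        t0, t1 = t[i], t[i + 1]
        d0, d1 = d[i], d[i + 1]
        seg = t1 - t0
        if d0 <= 0 and d1 <= 0:
            run += seg
        elif d0 <= 0 < d1:
            run += seg * d0 / (d0 - d1)  # exit crossing
            best = max(best, run)
            run = 0.0
        elif d0 > 0 >= d1:
            run = seg * d0 / (d0 - d1)
            run = seg - run  # time inside after entry crossing
        else:
            # possibly dips into the band between two outside samples —
            # a linear path cannot, so no dwell accrues
            best = max(best, run)
            run = 0.0
        best = max(best, run)
    return best


def _window_slice(t: np.ndarray, a: np.ndarray, w0: float, w1: float):
    """Clip a trajectory to [w0, w1] with interpolated endpoint samples."""
    if t[0] > w0 + 1e-9 or t[-1] < w1 - 1e-9:
        raise ValueError("trajectory does not cover the scoring window")
    inside = (t > w0) & (t < w1)
    tt = np.concatenate([[w0], t[inside], [w1]])
    aa = np.concatenate([[np.interp(w0, t, a)], a[inside], [np.interp(w1, t, a)]])
    if np.any(np.diff(tt) > MAX_GAP_S + 1e-9):
        raise ValueError("trajectory gap exceeds 0.2 s inside the scoring window")
    return tt, aa


def score_cue(
    t: np.ndarray,
    angle: np.ndarray,
    cue: CueEvent,
    tol: float = TOLERANCE_DEG,
    dwell_s: float = DWELL_S,
) -> CueScore:
    """Score one cue on a trajectory sampled at >= 10 Hz."""
    if cue.is_rest:
        w0, w1 = cue.onset_s + GRACE_S, cue.onset_s + REST_WINDOW_S + GRACE_S
    else:
        w0, w1 = cue.onset_s, cue.onset_s + MOVE_WINDOW_S
    tt, aa = _window_slice(np.asarray(t, float), np.asarray(angle, float), w0, w1)
    dwell = max_dwell_in_band(tt, aa, cue.target_angle_deg, tol)
    return CueScore(
        cue=cue,
        success=bool(dwell >= dwell_s),
        max_dwell_s=float(dwell),
        window_bounds_s=(w0, w1),
    )


def score_block(t: np.ndarray, angle: np.ndarray, cues) -> list[CueScore]:
    return [score_cue(t, angle, c) for c in cues]


def aggregate(scores) -> BlockScore:
    """Pool cue scores into counts, accuracy and binomial standard error."""
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to aggregate")
    per_angle: dict = {}
    k = 0
    for s in scores:
        key = ("rest" if s.cue.is_rest else "move", s.cue.target_angle_deg)
        succ, tot = per_angle.get(key, (0, 0))
        per_angle[key] = (succ + int(s.success), tot + 1)
        k += int(s.success)
    return BlockScore(per_angle=per_angle, total_correct=k, total=len(scores))


def accuracy_from_counts(k: int, n: int) -> tuple[float, float]:
    """Accuracy and binomial standard error, both in percent, from counts."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    return 100.0 * p, 100.0 * float(np.sqrt(p * (1.0 - p) / n))


def cdd(
    decoded_t: np.ndarray,
    decoded_deg: np.ndarray,
    achieved_deg: np.ndarray,
    cues,
) -> CddSummary:
    """Median and IQR of decoded-minus-achieved angle during movement windows.

    The two series must be sampled on the same time base.  Quantiles use
    linear interpolation (numpy's default, type 7).
    """
    td = np.asarray(decoded_t, float)
    d = np.asarray(decoded_deg, float)
    a = np.asarray(achieved_deg, float)
    if d.shape != a.shape or td.shape != d.shape:
        raise ValueError("decoded and achieved series must be time-aligned")
    mask = np.zeros(td.size, dtype=bool)
    for c in cues:
        if not c.is_rest:
            mask |= (td >= c.onset_s) & (td <= c.onset_s + MOVE_WINDOW_S)
    diff = d[mask] - a[mask]
    if diff.size == 0:
        raise ValueError("no samples inside movement windows")
    q1, q2, q3 = np.percentile(diff, [25, 50, 75])
    return CddSummary(median_deg=float(q2), iqr_deg=float(q3 - q1), n=int(diff.size))


def permutation_test_mwp(
    trials_a,
    trials_b,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided permutation test on the difference of condition means.

    Inputs are trial-mean MWP values per condition.  When the number of
    distinct label assignments is at most ``n_perm`` the test is exhaustive
    (exact p); otherwise ``n_perm`` random shuffles are drawn and the
    add-one estimator p = (1 + #{|d_perm| >= |d_obs|}) / (n_perm + 1) is
    returned.
    """
    a = np.asarray(trials_a, float)
    b = np.asarray(trials_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per condition")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    obs = abs(a.mean() - b.mean())
    total = comb(n, na)
    tol = 1e-12
    if total <= n_perm:
        count = 0
        idx = np.arange(n)
        for sel in combinations(idx, na):
            sa = pooled[list(sel)]
            stat = abs(sa.mean() - (pooled.sum() - sa.sum()) / (n - na))
            count += stat >= obs - tol
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        count += stat >= obs - tol
    return (1 + count) / (n_perm + 1)


def trial_mean_mwp(
    t: np.ndarray, mwp: np.ndarray, cues, t_from: float = 0.5, t_to: float = 2.5
) -> dict[float, np.ndarray]:
    """Per-condition trial means of a channel's MWP, 0.5-2.5 s post cue onset."""
    t = np.asarray(t, float)
    x = np.asarray(mwp, float)
    out: dict[float, list[float]] = {}
    for c in cues:
        m = (t >= c.onset_s + t_from) & (t <= c.onset_s + t_to)
        if m.any():
            out.setdefault(c.target_angle_deg, []).append(float(x[m].mean()))
    return {k: np.asarray(v) for k, v in out.items()}


def angle_force_correlation(angle_series, force_series) -> float:
    """Pearson correlation between wrist angle and load-cell force."""
    a = np.asarray(angle_series, float)
    f = np.asarray(force_series, float)
    if a.shape != f.shape:
        raise ValueError("series must be aligned")
    if np.std(a) == 0 or np.std(f) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(a, f)[0, 1])


def block_table(block_scores: dict[int, BlockScore], descriptions: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-block score table in the published layout (per-angle k/n, totals)."""
    rows = []
    for block_id, bs in sorted(block_scores.items()):
        row = {"block": block_id}
        if descriptions:
            row["description"] = descriptions.get(block_id, "")
        for (kind, ang), (succ, tot) in sorted(bs.per_angle.items()):
            label = "rest" if kind == "rest" else f"{ang:g}deg"
            row[label] = f"{succ}/{tot}"
        row["total_correct"] = f"{bs.total_correct}/{bs.total}"
        row["accuracy_pct"] = round(bs.accuracy_pct, 1)
        row["se_pct"] = round(bs.se_pct, 1)
        rows.append(row)
    return pd.DataFrame(rows)
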
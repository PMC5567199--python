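# gradedbci

Simulation and analysis pipeline for *graded* motor decoding with a
brain-computer interface driving functional electrical stimulation
(BCI-FES). The scientific setting: a person with tetraplegia has a
96-channel microelectrode array in primary motor cortex; the system must
decode not just *whether* to move but *how much* — a continuously graded
wrist-flexion angle standing in for contraction force — and stimulate the
forearm muscles to produce it against an elastic load. The package is for
researchers who want a fully synthetic, reproducible testbed for every
stage of that chain: no human recordings from this paradigm are public,
so the package generates its own angle-tuned neural signals and focuses
on making the *methods* exact and testable.

## What is implemented

- **Task design** — 24-cue blocks (3 × 4 target angles interleaved with
  rest), the 7-block imagined/virtual-protractor session and the 11-block
  FES session with training, test, recalibration and generalization
  phases.
- **Synthetic neural data** — 30 kHz raw voltage or 10 Hz feature-level
  streams with per-channel angle tuning (increasing, non-monotone,
  non-linear, flat classes), plus 20 Hz stimulation-artifact injection.
- **Preprocessing** — artifact detection by 4-of-12 sentinel-channel
  consensus at ±500 µV, 3.5 ms excision windows (≥82.5% of each 100 ms
  frame always retained), and the mean-wavelet-power (MWP) feature: db4
  levels 4–6 (234.375–1875 Hz at 30 kHz), mean |coefficient| per 100 ms,
  1 s boxcar, optional 15 s baseline subtraction, per channel-and-level
  z-scoring, averaged to 96 values per frame.
- **Decoders** — beta regression with a logit link,
  `logit(mu) = b0 + sum_j b_j MWP_j`, constant precision φ, fitted by
  monotone Fisher scoring with per-channel Wald tests; and RBF-kernel
  ε-SVR. Both are scikit-learn estimators (`fit`/`predict`, fitted
  attributes like `coef_`, `p_values_`, `phi_`) and compose with sklearn
  model selection.
- **FES plant** — decoded force → piecewise-linear calibration →
  0–20 mA, 20 Hz, 500 µs stimulation; a wrist plant with motor threshold,
  saturating recruitment, elastic-band load cell (0.3–0.7 lb) and a
  leaky fatigue accumulator; recalibration from amplitude-sweep history.
- **Evaluation** — the ±15° / 2 s dwell scoring rule with 6.5 s movement
  and 3.5 s rest windows, pooled accuracies with binomial standard
  errors, the calibration difference distribution (CDD, decoded minus
  achieved angle) with per-block median/IQR, and permutation tests on
  trial-mean MWP.
- **Session runners** — `run_virtual` and `run_fes` wire everything into
  deterministic end-to-end sessions (config + seed → byte-identical
  outputs), including the closed loop in which the simulated subject
  leans the imagined force on the observed wrist angle.

See `docs/methods.md` for the model details and parameter rationale.

## Worked example

Run a full simulated FES session from the shell:

```bash
gradedbci run --mode fes --seed 1 --out scratch/fes-demo
```

This prints the per-block score table and the pooled summaries:

```
 block    description 60deg 82deg 105deg 128deg  rest total_correct  accuracy_pct  se_pct ...
     1      open_loop   3/3   3/3    3/3    3/3 12/12         24/24         100.0     0.0
     2     volitional   3/3   2/3    0/3    3/3 12/12         20/24          83.3     7.6
     ...
     8           test   3/3   3/3    0/3    0/3 12/12         18/24          75.0     8.8
     9           test   3/3   3/3    3/3    0/3 12/12         21/24          87.5     6.8
     ...
training 3-5: 58/72 = 80.6 +/- 4.7%
test pre-recal 6-8: 57/72 = 79.2 +/- 4.8%
test post-recal 9-11: 63/72 = 87.5 +/- 3.9%
generalization 10-11: 42/48 = 87.5 +/- 4.8%
```

Each row counts successful cues (within 15° of the target for 2
continuous seconds) per angle; the pooled lines give accuracy with its
binomial standard error. The accumulating muscle fatigue shows up first
at the highest angles (the 128° column collapses across the test blocks
while 60° stays perfect), and the per-block CDD IQR written to
`summary.json` inflates across the pre-recalibration test blocks and
drops back after the stimulation is recalibrated — the signature that
the mismatch is muscular, not neural.

The same from Python:

```python
from gradedbci import SessionConfig, run_virtual

res = run_virtual(SessionConfig(mode="virtual", seed=1))
print(res.online_mae_deg)        # 6.4  (median |decoded - cued| deg, online blocks)
print(res.n_significant_05)      # 46   (channels with Wald p < 0.05, pooled fit)
print(res.lobo_mae_beta_deg,     # 6.1  leave-one-block-out median abs error
      res.lobo_mae_svr_deg)      # 7.1
res.coefficient_table()          # 96-row coefficient / p-value report
```

`gradedbci verify` prints the fixed pipeline arithmetic (wavelet band
edges, the 82.5% excision floor, and the accuracy/SE figures implied by
published-style counts).

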
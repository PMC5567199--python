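"""Cue sequences and session schedules.

Both experiments are organised in *blocks* of 24 consecutive 5 s cues:
12 non-rest cues (three repetitions of each of four target angles, in
seeded random order) strictly alternating with 12 rest cues, so every
movement cue is immediately followed by a rest cue.  A block therefore
lasts exactly 120 s.

The virtual-protractor experiment uses targets {52.5, 90, 127.5, 165}°
with rest at 0°; the FES experiment uses {60, 82, 105, 128}° with rest at
36° (the passive wrist position), moving the three intermediate angles to
{57, 76, 111} and {71, 90, 114} in the two generalization blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

CUE_DURATION_S = 5.0
CUES_PER_BLOCK = 24

#: Non-rest targets of the virtual-protractor experiment (degrees).
VIRTUAL_ANGLES = (52.5, 90.0, 127.5, 165.0)
VIRTUAL_REST = 0.0

#: Non-rest targets of the FES training/test blocks (degrees).
FES_ANGLES = (60.0, 82.0, 105.0, 128.0)
FES_REST = 36.0
FES_MAX = 128.0
#: Intermediate angles for the two generalization blocks (max angle kept).
GENERALIZATION_ANGLES = ((57.0, 76.0, 111.0, 128.0), (71.0, 90.0, 114.0, 128.0))

BLOCK_PURPOSES = ("open_loop", "volitional", "training", "test", "generalization")


@dataclass(frozen=True)
class CueEvent:
    """A single cue: hold ``target_angle_deg`` from ``onset_s`` for ``duration_s``."""

    target_angle_deg: float
    onset_s: float
    duration_s: float = CUE_DURATION_S
    is_rest: bool = False

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class BlockSpec:
    """Specification of one 24-cue block."""

    block_id: int
    purpose: str
    angle_set: tuple[float, ...]
    rest_angle_deg: float
    seed: int

    def __post_init__(self) -> None:
        if self.purpose not in BLOCK_PURPOSES:
            raise ValueError(f"unknown block purpose {self.purpose!r}")
        angles = tuple(float(a) for a in self.angle_set)
        if len(set(angles)) != 4:
            raise ValueError("angle_set must contain exactly 4 distinct angles")
        if any(a <= self.rest_angle_deg or a > 180.0 for a in angles):
            raise ValueError(
                "non-rest angles must lie in (rest_angle, 180] degrees"
            )
        object.__setattr__(self, "angle_set", angles)


def make_block(spec: BlockSpec, t0_s: float = 0.0) -> list[CueEvent]:
    """Build the ordered cue list for one block.

    The 12 non-rest cues are a seeded random permutation of the four target
    angles repeated three times each; each is immediately followed by a
    5 s rest cue, giving 24 contiguous cues (120 s).
    """
    rng = np.random.default_rng(spec.seed)
    targets = np.repeat(np.asarray(spec.angle_set, dtype=float), 3)
    order = rng.permutation(targets.size)
    cues: list[CueEvent] = []
    t = float(t0_s)
    for angle in targets[order]:
        cues.append(CueEvent(float(angle), t, CUE_DURATION_S, is_rest=False))
        t += CUE_DURATION_S
        cues.append(CueEvent(spec.rest_angle_deg, t, CUE_DURATION_S, is_rest=True))
        t += CUE_DURATION_S
    assert len(cues) == CUES_PER_BLOCK
    return cues


def make_session(base_seed: int = 0) -> list[BlockSpec]:
    """The 11-block FES session schedule.

    Block 1 is open-loop (stimulation follows the cue), block 2 is the first
    volitional block, blocks 3-5 train the decoder, blocks 6-9 are test
    blocks (stimulation is recalibrated between blocks 8 and 9), and blocks
    10-11 are generalization blocks with intermediate angles not used during
    training.
    """
    purposes = (
        ["open_loop", "volitional"] + ["training"] * 3 + ["test"] * 4
        + ["generalization"] * 2
    )
    blocks = []
    for i, purpose in enumerate(purposes):
        block_id = i + 1
        if purpose == "generalization":
            angle_set = GENERALIZATION_ANGLES[block_id - 10]
        else:
            angle_set = FES_ANGLES
        blocks.append(
            BlockSpec(
                block_id=block_id,
                purpose=purpose,
                angle_set=angle_set,
                rest_angle_deg=FES_REST,
                seed=int(base_seed) * 1000 + block_id,
            )
        )
    return blocks


def make_virtual_session(base_seed: int = 0, n_blocks: int = 7) -> list[BlockSpec]:
    """The virtual-protractor session: one open-loop block then decoded blocks.

    Seven blocks give 21 replicates of each of the four target angles.
    """
    blocks = []
    for i in range(n_blocks):
        block_id = i + 1
        purpose = "open_loop" if block_id == 1 else "volitional"
        blocks.append(
            BlockSpec(
                block_id=block_id,
                purpose=purpose,
                angle_set=VIRTUAL_ANGLES,
                rest_angle_deg=VIRTUAL_REST,
                seed=int(base_seed) * 1000 + block_id,
            )
        )
    return blocks


def session_to_json(blocks: Sequence[BlockSpec]) -> str:
    return json.dumps([asdict(b) for b in blocks], indent=1)


def session_from_json(text: str) -> list[BlockSpec]:
    return [BlockSpec(**{**d, "angle_set": tuple(d["angle_set"])}) for d in json.loads(text)]
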
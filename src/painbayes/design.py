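"""Block/trial schedules of the two conditioning experiments.

Experiment 1 (placebo only): 3 blocks of 12 stimuli. Blocks 1-2 condition
the cue-intensity contingencies (6 high+red, 6 low+green, shuffled); block 3
tests the placebo effect with high stimuli only (6 red, 6 green, shuffled).

Experiment 2 (no-cue test + placebo): 4 blocks of 16 stimuli. Blocks 1-2
condition (8 high+red, 8 low+green); block 3 delivers uncued stimuli —
4 high, 4 low and 8 intermediate, all paired with a neutral cue, in random
order; block 4 is the placebo test (8 high+red, 8 high+green, shuffled).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import InputError
from .observer import CueCondition

__all__ = ["Trial", "ExperimentDesign", "make_design"]


class Trial(NamedTuple):
    cue: CueCondition
    level: str  # "low" | "mid" | "high"


#: block compositions, in canonical (unshuffled) order
_COMPOSITIONS = {
    1: [
        [Trial(CueCondition.RED, "high")] * 6 + [Trial(CueCondition.GREEN, "low")] * 6,
        [Trial(CueCondition.RED, "high")] * 6 + [Trial(CueCondition.GREEN, "low")] * 6,
        [Trial(CueCondition.RED, "high")] * 6 + [Trial(CueCondition.GREEN, "high")] * 6,
    ],
    2: [
        [Trial(CueCondition.RED, "high")] * 8 + [Trial(CueCondition.GREEN, "low")] * 8,
        [Trial(CueCondition.RED, "high")] * 8 + [Trial(CueCondition.GREEN, "low")] * 8,
        [Trial(CueCondition.NONE, "high")] * 4
        + [Trial(CueCondition.NONE, "low")] * 4
        + [Trial(CueCondition.NONE, "mid")] * 8,
        [Trial(CueCondition.RED, "high")] * 8 + [Trial(CueCondition.GREEN, "high")] * 8,
    ],
}

#: number of blocks that are conditioning (training) blocks, per experiment
N_CONDITIONING_BLOCKS = 2


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered blocks of (cue, stimulus level) trials for one subject."""

    experiment: int
    blocks: tuple[tuple[Trial, ...], ...]

    def __post_init__(self) -> None:
        if self.experiment not in _COMPOSITIONS:
            raise InputError(f"unknown experiment id {self.experiment}; expected 1 or 2")
        expected = _COMPOSITIONS[self.experiment]
        if len(self.blocks) != len(expected):
            raise InputError(
                f"experiment {self.experiment} has {len(expected)} blocks, got {len(self.blocks)}"
            )
        for i, (block, ref) in enumerate(zip(self.blocks, expected)):
            if sorted(block) != sorted(ref):
                raise InputError(f"block {i} composition does not match the design")

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def conditioning_blocks(self) -> tuple[int, ...]:
        return tuple(range(N_CONDITIONING_BLOCKS))

    @property
    def test_blocks(self) -> tuple[int, ...]:
        return tuple(range(N_CONDITIONING_BLOCKS, len(self.blocks)))

    @property
    def placebo_block(self) -> int:
        """Index of the all-high red/green test block."""
        return 2 if self.experiment == 1 else 3

    @property
    def midblue_block(self) -> int | None:
        """Index of the uncued mixed-intensity block (Experiment 2 only)."""
        return 2 if self.experiment == 2 else None


def make_design(experiment: int, seed: int) -> ExperimentDesign:
    """Seeded trial schedule: each block is an independent permutation."""
    if experiment not in _COMPOSITIONS:
        raise InputError(f"unknown experiment id {experiment}; expected 1 or 2")
    rng = np.random.default_rng(seed)
    blocks = []
    for comp in _COMPOSITIONS[experiment]:
        order = rng.permutation(len(comp))
        blocks.append(tuple(comp[i] for i in order))
    return ExperimentDesign(experiment, tuple(blocks))
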
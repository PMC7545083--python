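"""Divided-field trial schedules and cohort counterbalancing.

Each experiment is two blocks (face, flower) of 256 trials; every unique
image appears once per block, in random order.  Experiment 1 presents signal
and noise-only trials 1:1 (128 + 128); Experiment 2 presents them 1:3
(64 + 192).  Stimuli are lateralized: signal trials inherit their hemifield
from the image's placement, noise-only trials are assigned a hemifield so
each block is balanced left/right within stimulus type.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import StimulusSet, location_side

__all__ = [
    "Trial",
    "TrialSchedule",
    "CounterbalanceSpec",
    "build_block_schedule",
    "build_subject_schedule",
    "counterbalance_cohort",
    "schedule_to_frame",
    "SIGNAL_TRIALS",
    "NOISE_TRIALS",
    "BLOCK_LENGTH",
]

BLOCK_LENGTH = 256
SIGNAL_TRIALS = {1: 128, 2: 64}
NOISE_TRIALS = {1: 128, 2: 192}

DURATION_MS = 180.0
ITI_MS = 1000.0


@dataclass
class Trial:
    index: int
    block: str                   # "face" | "flower"
    stimulus_type: str           # "signal" | "noise_only"
    visual_field: str            # "LVF" | "RVF"
    image_ref: str | None
    noise_fraction: float | None
    location_id: int | None
    duration_ms: float = DURATION_MS
    iti_ms: float = ITI_MS
    practice: bool = False


@dataclass(frozen=True)
class CounterbalanceSpec:
    block_order: str             # "face_first" | "flower_first"
    response_mapping: str        # "up_present" | "down_present"
    responding_hand: str         # "left" | "right"


@dataclass
class TrialSchedule:
    subject_id: int
    experiment: int
    blocks: dict                 # category -> list[Trial], in presentation order
    counterbalance: CounterbalanceSpec

    @property
    def block_sequence(self) -> list[str]:
        first = "face" if self.counterbalance.block_order == "face_first" else "flower"
        second = "flower" if first == "face" else "face"
        return [first, second]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        schedule_to_frame(self).to_csv(
            out / f"subject{self.subject_id:03d}_schedule.csv", index=False
        )
        with open(out / f"subject{self.subject_id:03d}_counterbalance.json", "w") as fh:
            json.dump(asdict(self.counterbalance), fh, indent=2)


def _side_to_vf(side: str) -> str:
    return "LVF" if side == "left" else "RVF"


def build_block_schedule(
    experiment: int,
    block: str,
    stimulus_set: StimulusSet | None = None,
    seed=None,
) -> list[Trial]:
    """One block of 256 trials in seeded random order.

    With a :class:`StimulusSet`, trials reference concrete manifest ids and
    the Experiment-2 signal subset is drawn balanced over identity x noise
    level x hemifield (16 cells x 4 images).  Without one, an abstract
    schedule with the same composition (for simulation studies) is built.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    rng = np.random.default_rng(seed)
    n_signal, n_noise = SIGNAL_TRIALS[experiment], NOISE_TRIALS[experiment]

    trials: list[Trial] = []
    if stimulus_set is not None:
        signals = [c for c in stimulus_set.composites if c.category == block]
        noises = [c for c in stimulus_set.noise_only if c.category == block]
        if len(noises) < n_noise:
            raise ValueError(
                f"need {n_noise} unique noise-only images for the {block} "
                f"block, stimulus set provides {len(noises)}"
            )
        if experiment == 1:
            chosen = signals
        else:
            # balanced subset: 4 per (identity, level, side) cell
            chosen = []
            keyfn = lambda c: (c.identity, c.noise_fraction, location_side(c.location_id))
            cells: dict = {}
            for c in signals:
                cells.setdefault(keyfn(c), []).append(c)
            per_cell, rem = divmod(n_signal, len(cells))
            if rem:
                raise ValueError("signal count not divisible over design cells")
            for key in sorted(cells, key=str):
                pool = cells[key]
                take = rng.choice(len(pool), size=per_cell, replace=False)
                chosen.extend(pool[i] for i in sorted(take))
        if len(chosen) != n_signal:
            raise ValueError(
                f"need {n_signal} signal images, have {len(chosen)}"
            )
        for c in chosen:
            trials.append(
                Trial(0, block, "signal", _side_to_vf(location_side(c.location_id)),
                      c.image_id, c.noise_fraction, c.location_id)
            )
        noise_pool = noises[:n_noise]
        vfs = ["LVF", "RVF"] * (n_noise // 2)
        for c, vf in zip(noise_pool, vfs):
            trials.append(Trial(0, block, "noise_only", vf, c.image_id, None, None))
    else:
        levels = _abstract_levels(block)
        per = n_signal // (len(levels) * 2)
        for level, side in itertools.product(levels, ("left", "right")):
            for _ in range(per):
                loc = rng.integers(0, 4) + (0 if side == "left" else 4)
                trials.append(
                    Trial(0, block, "signal", _side_to_vf(side), None, level, int(loc))
                )
        for vf in ["LVF", "RVF"] * (n_noise // 2):
            trials.append(Trial(0, block, "noise_only", vf, None, None, None))

    order = rng.permutation(len(trials))
    shuffled = [trials[i] for i in order]
    for i, t in enumerate(shuffled):
        t.index = i
    return shuffled


def _abstract_levels(block: str):
    from .stimuli import DEFAULT_NOISE_LEVELS

    return DEFAULT_NOISE_LEVELS[block]


def build_subject_schedule(
    subject_id: int,
    experiment: int,
    counterbalance: CounterbalanceSpec,
    stimulus_set: StimulusSet | None = None,
    seed=None,
    practice_trials: int = 8,
) -> TrialSchedule:
    """Two counterbalanced blocks for one subject, with practice trials
    flagged at the head of the first block (excluded from analysis)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(3)
    blocks = {}
    for cat, s in zip(("face", "flower"), seeds):
        blocks[cat] = build_block_schedule(experiment, cat, stimulus_set, s)
    if practice_trials:
        rng = np.random.default_rng(seeds[2])
        first = ("face" if counterbalance.block_order == "face_first" else "flower")
        practice = []
        for i in range(practice_trials):
            st = "signal" if rng.random() < 0.5 else "noise_only"
            vf = "LVF" if rng.random() < 0.5 else "RVF"
            level = float(rng.choice(_abstract_levels(first))) if st == "signal" else None
            loc = int(rng.integers(0, 8)) if st == "signal" else None
            practice.append(
                Trial(-(practice_trials - i), first, st, vf, None, level, loc,
                      practice=True)
            )
        blocks[first] = practice + blocks[first]
    return TrialSchedule(subject_id, experiment, blocks, counterbalance)


def counterbalance_cohort(n_subjects: int, seed=None) -> list[CounterbalanceSpec]:
    """Assign the 8 cells of block order x response mapping x responding hand
    as evenly as possible across the cohort (seeded cell order)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    rng = np.random.default_rng(seed)
    cells = [
        CounterbalanceSpec(bo, rm, hand)
        for bo in ("face_first", "flower_first")
        for rm in ("up_present", "down_present")
        for hand in ("left", "right")
    ]
    order = rng.permutation(len(cells))
    specs = [cells[order[i % 8]] for i in range(n_subjects)]
    return specs


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """Flatten a schedule to one row per trial in presentation order."""
    rows = []
    for cat in schedule.block_sequence:
        for t in schedule.blocks[cat]:
            rows.append(
                {
                    "subject_id": schedule.subject_id,
                    "experiment": schedule.experiment,
                    "block": t.block,
                    "trial": t.index,
                    "stimulus_type": t.stimulus_type,
                    "visual_field": t.visual_field,
                    "image_ref": t.image_ref,
                    "noise_fraction": t.noise_fraction,
                    "location_id": t.location_id,
                    "practice": t.practice,
                }
            )
    return pd.DataFrame(rows)
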
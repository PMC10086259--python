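"""Lateralized letter-matching task schedule and pathway labelling.

Two letters appear briefly in two of four corner positions around a
central fixation; the participant reports match/non-match by keypress,
switching the response hand halfway through the task. Trials whose two
letters both fall in one visual hemifield are the unilateral trials used
for transfer-time analysis; for those, each stimulus-response-hand (RT)
or stimulus-electrode (ERP) combination is either *direct* (no callosal
relay) or *indirect* (requires interhemispheric transfer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CORNERS",
    "CORNER_PAIRS",
    "TaskConfig",
    "TrialSpec",
    "generate_schedule",
    "label_visual_field",
    "label_rt_pathway",
    "label_erp_pathway",
    "schedule_frame",
]

#: The four corner positions: upper/lower x left/right of fixation.
CORNERS = ("UL", "LL", "UR", "LR")

#: The six unordered corner pairs, in canonical order. The first is the
#: all-left pair, the second the all-right pair, the remaining four are
#: bilateral.
CORNER_PAIRS = (
    ("UL", "LL"),
    ("UR", "LR"),
    ("UL", "UR"),
    ("UL", "LR"),
    ("LL", "UR"),
    ("LL", "LR"),
)

_LEFT = {"UL", "LL"}
_RIGHT = {"UR", "LR"}


@dataclass
class TaskConfig:
    """Design parameters of the letter-matching task.

    Defaults give 8 blocks x 48 trials = 384 analysed trials plus 10
    practice trials, a 60 ms stimulus, 500 ms fixation, and a 1500-2000 ms
    jittered intertrial interval. ``pair_weights`` sets the sampling
    probability of each entry of :data:`CORNER_PAIRS` (uniform by
    default, i.e. 1/3 of trials unilateral). Geometry fields document the
    display; nothing is rendered.
    """

    n_blocks: int = 8
    trials_per_block: int = 48
    n_practice: int = 10
    stimulus_ms: float = 60.0
    fixation_ms: float = 500.0
    iti_range_ms: tuple[float, float] = (1500.0, 2000.0)
    letter_set: tuple[str, ...] = ("A", "B")
    pair_weights: tuple[float, ...] | None = None
    start_hand: str = "left"
    hand_switch_at_trial: int | None = None  # default: midpoint
    viewing_distance_in: float = 20.0
    geometry: dict = field(default_factory=lambda: {
        "horizontal_offset": "2deg19min",
        "vertical_offset": "1deg56min",
        "letter_height": "27min",
        "fixation": "25x40min",
    })

    def __post_init__(self) -> None:
        if self.iti_range_ms[0] > self.iti_range_ms[1]:
            raise ValueError("iti_range_ms bounds must be ordered")
        if self.start_hand not in ("left", "right"):
            raise ValueError("start_hand must be 'left' or 'right'")
        if self.pair_weights is not None:
            w = np.asarray(self.pair_weights, dtype=float)
            if w.shape != (6,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("pair_weights must be 6 non-negative weights")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class TrialSpec:
    """One trial of the task schedule."""

    trial_id: int
    block: int  # 0 for practice trials
    position_pair: tuple[str, str]
    letters: tuple[str, str]
    match: bool
    assigned_hand: str
    practice: bool = False

    def __post_init__(self) -> None:
        a, b = self.position_pair
        if a == b or a not in CORNERS or b not in CORNERS:
            raise ValueError(f"invalid position pair {self.position_pair}")
        if self.match != (self.letters[0].upper() == self.letters[1].upper()):
            raise ValueError("match flag inconsistent with letters")

    @property
    def visual_field(self) -> str:
        return label_visual_field(self.position_pair)


def label_visual_field(position_pair: tuple[str, str]) -> str:
    """LVF iff both corners are left of fixation, RVF iff both right."""
    pair = set(position_pair)
    if pair <= _LEFT:
        return "LVF"
    if pair <= _RIGHT:
        return "RVF"
    return "bilateral"


def label_rt_pathway(visual_field: str, hand: str) -> str:
    """Direct iff the responding hand is contralateral to the stimulus
    (RVF/right or LVF/left: the stimulated hemisphere drives the response
    without callosal relay)."""
    if visual_field not in ("LVF", "RVF"):
        raise ValueError(f"pathway undefined for visual_field={visual_field!r}")
    if hand not in ("left", "right"):
        raise ValueError(f"unknown hand {hand!r}")
    direct = (visual_field == "RVF" and hand == "right") or (
        visual_field == "LVF" and hand == "left"
    )
    return "direct" if direct else "indirect"


def label_erp_pathway(visual_field: str, electrode: int, montage=None) -> str:
    """Direct iff the ROI electrode is contralateral to the stimulated
    field (LVF -> right-occipital, RVF -> left-occipital)."""
    if visual_field not in ("LVF", "RVF"):
        raise ValueError(f"pathway undefined for visual_field={visual_field!r}")
    if montage is None:
        left_occ, right_occ = 65, 90
    else:
        left_occ, right_occ = montage.left_occipital, montage.right_occipital
    if electrode not in (left_occ, right_occ):
        raise ValueError(f"electrode {electrode} is not an ROI electrode")
    direct = (visual_field == "LVF" and electrode == right_occ) or (
        visual_field == "RVF" and electrode == left_occ
    )
    return "direct" if direct else "indirect"


def _draw_letters(rng: np.random.Generator, match: bool, letter_set) -> tuple[str, str]:
    # case is assigned uniformly at random, independent of match status
    if match:
        base = rng.choice(letter_set)
        pair = (base, base)
    else:
        pair = tuple(rng.choice(letter_set, size=2, replace=False))
    return tuple(
        letter.lower() if rng.random() < 0.5 else letter.upper() for letter in pair
    )


def generate_schedule(config: TaskConfig, seed: int) -> list[TrialSpec]:
    """Generate the full trial schedule, deterministic in ``seed``.

    Practice trials (flagged, ``block=0``) precede the task blocks and are
    excluded from all analyses. Match/non-match is balanced 50/50 within
    every block; position pairs are drawn from ``config.pair_weights``.
    The response hand starts at ``config.start_hand`` and switches at the
    midpoint of the analysed trials.
    """
    if config.trials_per_block % 2:
        raise ValueError("trials_per_block must be even for 50/50 match balance")
    rng = np.random.default_rng(seed)
    weights = (
        np.full(6, 1 / 6)
        if config.pair_weights is None
        else np.asarray(config.pair_weights, dtype=float)
    )
    weights = weights / weights.sum()
    switch_at = (
        config.n_trials // 2
        if config.hand_switch_at_trial is None
        else config.hand_switch_at_trial
    )
    other = "right" if config.start_hand == "left" else "left"

    trials: list[TrialSpec] = []
    tid = 0
    for p in range(config.n_practice):
        tid += 1
        match = bool(rng.random() < 0.5)
        trials.append(TrialSpec(
            trial_id=tid,
            block=0,
            position_pair=CORNER_PAIRS[rng.choice(6, p=weights)],
            letters=_draw_letters(rng, match, config.letter_set),
            match=match,
            assigned_hand=config.start_hand,
            practice=True,
        ))
    task_index = 0
    for b in range(1, config.n_blocks + 1):
        flags = np.array([True] * (config.trials_per_block // 2)
                         + [False] * (config.trials_per_block // 2))
        rng.shuffle(flags)
        for match in flags:
            tid += 1
            task_index += 1
            hand = config.start_hand if task_index <= switch_at else other
            trials.append(TrialSpec(
                trial_id=tid,
                block=b,
                position_pair=CORNER_PAIRS[rng.choice(6, p=weights)],
                letters=_draw_letters(rng, bool(match), config.letter_set),
                match=bool(match),
                assigned_hand=hand,
            ))
    return trials


def schedule_frame(schedule: list[TrialSpec]) -> pd.DataFrame:
    """Tabular view of a schedule (one row per trial)."""
    return pd.DataFrame({
        "trial_id": [t.trial_id for t in schedule],
        "block": [t.block for t in schedule],
        "position_pair": ["+".join(t.position_pair) for t in schedule],
        "letters": ["".join(t.letters) for t in schedule],
        "match": [t.match for t in schedule],
        "visual_field": [t.visual_field for t in schedule],
        "assigned_hand": [t.assigned_hand for t in schedule],
        "practice": [t.practice for t in schedule],
    })
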
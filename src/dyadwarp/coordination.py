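"""Coordination scores from pairwise DTW distances.

A part's coordination score is the *inverted* normalized DTW distance
(multiplied by −1) between the interviewer's and interviewee's screened
streams, so that greater scores mean more coordination and 0 is the maximum
(identical movement).  The main analysis uses four pairings — head, torso
and the two same-label hand pairings — and summarizes a dyad×task as their
arithmetic mean; when a part's score is missing (sensor failure), the mean
of the available parts is used instead.  The cross-hand pairings
(interviewer left ↔ interviewee right and vice versa) are exploratory
variants reported alongside but never entering the aggregate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dtw_engine import StepPattern, dtw_align, rj_step_pattern
from .errors import DyadwarpError, PreprocessError
from .preprocess import DEFAULT_CONFIG, CleanSegment, preprocess_pair
from .sensor_io import DyadSession

logger = logging.getLogger("dyadwarp.coordination")

# pairing label -> (interviewer site, interviewee site)
PAIRINGS = {
    "head": ("head", "head"),
    "torso": ("torso", "torso"),
    "handLL": ("left_wrist", "left_wrist"),
    "handRR": ("right_wrist", "right_wrist"),
    "handLR": ("left_wrist", "right_wrist"),
    "handRL": ("right_wrist", "left_wrist"),
}
MAIN_PARTS = ("head", "torso", "handLL", "handRR")
CROSS_PARTS = ("handLR", "handRL")

HAND_MODES = {
    "same_label": MAIN_PARTS,
    "cross": ("head", "torso") + CROSS_PARTS,
    "both": MAIN_PARTS + CROSS_PARTS,
}


@dataclass
class CoordinationScore:
    """Per-part and aggregate coordination for one dyad×task."""

    dyad_id: str
    task: str
    part_scores: Dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def aggregate(self) -> float:
        """Mean of the available main-analysis parts (missing-data rule)."""
        avail = [
            v for k, v in self.part_scores.items() if k in MAIN_PARTS and v is not None
        ]
        if not avail:
            raise DyadwarpError(
                f"dyad {self.dyad_id} task {self.task}: no body-part score available"
            )
        return float(np.mean(avail))


def score_part(
    pair: Tuple[CleanSegment, CleanSegment], pattern: Optional[StepPattern] = None
) -> float:
    """−1 × normalized DTW distance for one preprocessed stream pair."""
    pattern = pattern or rj_step_pattern(6, "c")
    a, b = pair
    return -dtw_align(a.frames, b.frames, pattern).normalized_distance


def score_dyad_task(
    session: DyadSession,
    task: str,
    pattern: Optional[StepPattern] = None,
    hand_mode: str = "same_label",
    valid_range=DEFAULT_CONFIG["valid_range"],
) -> CoordinationScore:
    """Coordination score for one dyad×task.

    Computes head, torso and the hand pairings selected by ``hand_mode``
    ({'same_label', 'cross', 'both'}); parts whose streams are absent or
    unusable are recorded as missing, never imputed as zero.
    """
    if hand_mode not in HAND_MODES:
        raise DyadwarpError(f"unknown hand_mode {hand_mode!r}; use {sorted(HAND_MODES)}")
    pattern = pattern or rj_step_pattern(6, "c")
    score = CoordinationScore(dyad_id=session.dyad_id, task=task)
    for label in HAND_MODES[hand_mode]:
        site_a, site_b = PAIRINGS[label]
        try:
            pair = preprocess_pair(
                session, task, site_a, valid_range=valid_range, site_b=site_b
            )
        except PreprocessError as exc:
            logger.warning("dyad %s task %s %s: %s", session.dyad_id, task, label, exc)
            score.part_scores[label] = None
            continue
        score.part_scores[label] = score_part(pair, pattern)
    if all(v is None for v in score.part_scores.values()):
        raise DyadwarpError(
            f"dyad {session.dyad_id} task {task}: zero available body parts"
        )
    return score


def score_table(
    sessions: Iterable[DyadSession],
    pattern: Optional[StepPattern] = None,
    hand_mode: str = "same_label",
    valid_range=DEFAULT_CONFIG["valid_range"],
) -> pd.DataFrame:
    """Long-format score table: one row per dyad×task.

    Columns: dyad_id, task, order_variant, attention_instruction, one column
    per pairing label (NaN = missing), aggregate.  Row order is
    deterministic: sessions in input order, tasks in marker order.
    """
    pattern = pattern or rj_step_pattern(6, "c")
    labels = HAND_MODES[hand_mode] if hand_mode in HAND_MODES else None
    if labels is None:
        raise DyadwarpError(f"unknown hand_mode {hand_mode!r}")
    rows: List[dict] = []
    for session in sessions:
        for task in session.tasks:
            sc = score_dyad_task(
                session, task, pattern=pattern, hand_mode=hand_mode, valid_range=valid_range
            )
            row = {
                "dyad_id": session.dyad_id,
                "task": task,
                "order_variant": session.conditions.get("order_variant"),
                "attention_instruction": session.conditions.get("attention_instruction"),
            }
            for label in labels:
                v = sc.part_scores.get(label)
                row[label] = math.nan if v is None else v
            row["aggregate"] = sc.aggregate
            rows.append(row)
    cols = ["dyad_id", "task", "order_variant", "attention_instruction"]
    cols += list(labels) + ["aggregate"]
    return pd.DataFrame(rows, columns=cols)
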
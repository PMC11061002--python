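"""Scoring of the self-report instruments and the delay-discounting staircase.

Five instruments are supported at score level (item wordings are not
reproduced):

* AUDIT — 10-item alcohol-use screen, items 0-4, total 0-40;
* GHQ-12 — 12-item distress screen, Likert-scored 0-3, total 0-36;
* WHO-5 — 5-item well-being index, items 0-5, raw total 0-25;
* FINLIT — 9 financial-literacy items with a configurable per-item range
  (the published total scale for this battery is not standard, so the
  scoring map is a parameter rather than a guess);
* ED50 — the 5-trial adjusting-delay discounting elicitation.

The ED50 staircase asks five forced choices between a smaller-sooner reward
($500 now) and $1,000 at a probed delay. Probes walk a fixed 31-step
geometric ladder of delays from 1 hour to 25 years, starting at the ladder
midpoint; a "now" choice (the delayed reward is worth less than half)
moves the next probe to a shorter delay, a "delayed" choice to a longer
one, with the index step halving 8, 4, 2, 1, 1. The final index is the
delay at which the $1,000 loses half its value (ED50); the hyperbolic
discount rate is k = 1 / ED50 (1/days) and analyses use log k (natural
log). The ladder is committed as a data file so traces are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentSpec",
    "INSTRUMENTS",
    "DiscountingProfile",
    "score_instrument",
    "run_ed50_elicitation",
    "ed50_ladder",
    "cronbach_alpha",
    "LOG_K_MIN",
    "LOG_K_MAX",
]


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    n_items: int
    item_min: int
    item_max: int

    @property
    def total_range(self) -> tuple[int, int]:
        return self.n_items * self.item_min, self.n_items * self.item_max


INSTRUMENTS: dict[str, InstrumentSpec] = {
    "AUDIT": InstrumentSpec("AUDIT", 10, 0, 4),
    "GHQ12": InstrumentSpec("GHQ12", 12, 0, 3),
    "WHO5": InstrumentSpec("WHO5", 5, 0, 5),
    # item range configurable; 0-7 per item gives a 0-63 total consistent
    # with the reported cohort mean of 34.3
    "FINLIT": InstrumentSpec("FINLIT", 9, 0, 7),
}


@lru_cache(maxsize=1)
def ed50_ladder() -> np.ndarray:
    """The committed 31-step geometric delay ladder, in days."""
    with resources.files("harvestgame.data").joinpath("ed50_ladder.csv").open() as f:
        table = pd.read_csv(f)
    return table["delay_days"].to_numpy()


_LADDER_START_INDEX = 15  # midpoint of the 31-step ladder
_LADDER_STEPS = (8, 4, 2, 1, 1)

#: Reachable log-k bounds implied by the 1-hour / 25-year ladder ends.
LOG_K_MAX = float(np.log(24.0))  # ED50 of 1 hour
LOG_K_MIN = float(np.log(1.0 / 9125.0))  # ED50 of 25 years


@dataclass(frozen=True)
class DiscountingProfile:
    """ED50 delay with its hyperbolic rate: k = 1/ED50, log_k = ln k."""

    ed50_delay: float  # days
    k: float  # 1/days
    log_k: float

    @classmethod
    def from_delay(cls, delay_days: float) -> "DiscountingProfile":
        k = 1.0 / delay_days
        return cls(ed50_delay=delay_days, k=k, log_k=float(np.log(k)))


def score_instrument(responses: Sequence[int], spec: InstrumentSpec) -> int:
    """Summated-scale total for one participant's item responses."""
    if len(responses) != spec.n_items:
        raise ValueError(
            f"{spec.name} expects {spec.n_items} items, got {len(responses)}"
        )
    total = 0
    for i, r in enumerate(responses):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            raise ValueError(f"{spec.name} item {i + 1} is missing")
        if not spec.item_min <= r <= spec.item_max:
            raise ValueError(
                f"{spec.name} item {i + 1} response {r!r} outside "
                f"[{spec.item_min}, {spec.item_max}]"
            )
        total += int(r)
    return total


def _parse_answer(answer) -> bool:
    """True for 'delayed' (patient), False for 'now' (impulsive)."""
    if isinstance(answer, str):
        a = answer.strip().lower()
        if a in {"now", "n", "0"}:
            return False
        if a in {"delayed", "later", "d", "1"}:
            return True
        raise ValueError(f"unrecognized choice {answer!r}; use 'now' or 'delayed'")
    return bool(answer)


def run_ed50_elicitation(answers: Sequence) -> DiscountingProfile:
    """Score the 5-trial adjusting-delay staircase.

    ``answers`` are five choices, each ``"now"``/``"delayed"`` (or
    falsy/truthy). The probe index starts at the ladder midpoint and moves
    down (shorter delay) on "now", up on "delayed", by steps 8, 4, 2, 1, 1,
    clamped to the ladder ends. Five "now" answers reach the 1-hour floor
    (log k = ln 24); five "delayed" answers reach the 25-year ceiling
    (log k = ln(1/9125)).
    """
    if len(answers) != len(_LADDER_STEPS):
        raise ValueError(f"expected {len(_LADDER_STEPS)} answers, got {len(answers)}")
    ladder = ed50_ladder()
    index = _LADDER_START_INDEX
    for answer, step in zip(answers, _LADDER_STEPS):
        direction = 1 if _parse_answer(answer) else -1
        index = int(np.clip(index + direction * step, 0, len(ladder) - 1))
    return DiscountingProfile.from_delay(float(ladder[index]))


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Internal consistency: alpha = k/(k-1) * (1 - sum(var_i) / var_total).

    Sample variances use the n-1 denominator. Requires at least two items,
    two participants, and a non-degenerate total score.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("item_matrix must be (>=2 participants, >=2 items)")
    if np.isnan(x).any():
        raise ValueError("item_matrix contains missing values")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha is undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def score_long_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a long item-level table into a wide per-participant table.

    Expects columns ``participant_id, instrument, item_index, response``;
    ED50 rows carry the five staircase choices (0 = now, 1 = delayed) in
    ``response`` ordered by ``item_index``. Returns one row per participant
    with one column per instrument total plus ``log_k``.
    """
    required = {"participant_id", "instrument", "item_index", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for pid, group in responses.groupby("participant_id", sort=True):
        record: dict = {"participant_id": pid}
        for name, items in group.groupby("instrument"):
            vals = items.sort_values("item_index")["response"].tolist()
            if name == "ED50":
                record["log_k"] = run_ed50_elicitation(vals).log_k
            else:
                record[name.lower()] = score_instrument(vals, INSTRUMENTS[name])
        rows.append(record)
    return pd.DataFrame(rows)
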
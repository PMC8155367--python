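"""Grooved pegboard scoring per hand.

The grooved pegboard is a 25-peg keyed dexterity board; the score is the
time to place all pegs, plus counts of pegs placed and dropped.  Testing is
terminated administratively at 300 s: participants who do not complete the
board are recorded at the cap with the number of pegs they placed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

N_PEGS = 25
DEFAULT_CAP_S = 300.0


@dataclass
class PegboardResult:
    hand: str
    time_s: float
    pegs_placed: int
    pegs_dropped: int


def summarize_pegboard(
    raw_time_s: float,
    pegs_placed: int,
    pegs_dropped: int,
    hand: str = "non_dominant",
    cap_s: float = DEFAULT_CAP_S,
) -> PegboardResult:
    """Apply the administrative time cap and validate count ranges.

    Completed boards (all 25 pegs) keep their completion time, capped at
    ``cap_s``; incomplete boards are recorded at the cap.  No completion
    time is extrapolated for incomplete boards.
    """
    if not raw_time_s > 0:
        raise ValidationError("raw_time_s must be positive")
    if not 0 <= pegs_placed <= N_PEGS:
        raise ValidationError(f"pegs_placed must be in [0, {N_PEGS}], got {pegs_placed}")
    if pegs_dropped < 0:
        raise ValidationError("pegs_dropped must be non-negative")
    if pegs_placed < N_PEGS:
        time_s = cap_s
    else:
        time_s = min(float(raw_time_s), cap_s)
    return PegboardResult(hand, time_s, int(pegs_placed), int(pegs_dropped))
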
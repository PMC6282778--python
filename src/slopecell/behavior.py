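"""Trial segmentation, inclusion filters, and behavioural summaries.

A trial is one end-to-end shuttle: the animal leaves one endzone,
crosses the 103 cm running ROI, and enters the opposite endzone.
Excursions that turn around mid-track are marked excluded
("incomplete"), and completed trials slower than 15 cm/s on average
(duration > 7 s over the ROI) are marked excluded ("slow").  A trial is
"uphill" when it departs from the ground-level endzone of its block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import DOWNHILL, UPHILL, Condition, TrackGeometry
from .session_io import ConditionBlock, Session

__all__ = ["Trial", "segment_trials", "apply_trial_filters", "occupied_extent",
           "trials_for_condition", "MAX_TRIAL_DURATION_S"]

MAX_TRIAL_DURATION_S = 7.0


@dataclass(frozen=True)
class Trial:
    trial_id: int
    block_id: int
    tilt: int
    direction: str
    t_start: float
    t_end: float
    duration: float
    mean_speed: float  # ROI length / duration (cm/s); NaN if incomplete
    included: bool
    reason: str | None

    @property
    def condition(self) -> Condition:
        return Condition(self.tilt, self.direction)


def segment_trials(session: Session) -> list[Trial]:
    """Cut the position stream into end-to-end trials, one list per session.

    Trial boundaries are half-open in time: the first sample past the
    origin endzone boundary starts the trial and the first sample past
    the opposite boundary ends it.
    """
    g = session.geometry
    t = session.positions_t
    x = session.positions_x
    trials: list[Trial] = []
    trial_id = 0
    for block in session.schedule:
        sel = (t >= block.t_start) & (t < block.t_end)
        tb, xb = t[sel], x[sel]
        if tb.size == 0:
            continue
        # zone code per sample: -1 south endzone, 0 ROI, +1 north endzone
        zone = np.zeros(xb.size, dtype=int)
        zone[xb < g.roi_start_cm] = -1
        zone[xb >= g.roi_end_cm] = 1
        trial_id = _segment_block(trials, trial_id, block, g, tb, zone)
    return trials


def _segment_block(trials, trial_id, block: ConditionBlock, g: TrackGeometry,
                   tb: np.ndarray, zone: np.ndarray) -> int:
    ground_is_south = block.elevated_end == "north"
    origin = None  # endzone the current excursion departed from (-1/+1)
    t_entry = None
    for i in range(zone.size):
        z = zone[i]
        if origin is None:
            if z != 0:
                origin = z
            continue
        if z == 0:
            if t_entry is None:
                t_entry = tb[i]  # first sample inside the ROI
            continue
        if t_entry is None:
            origin = z
            continue
        # excursion resolved: reached z, departed from origin
        complete = z == -origin
        t_exit = tb[i]
        duration = float(t_exit - t_entry)
        departed_ground = (origin == -1) == ground_is_south
        direction = UPHILL if departed_ground else DOWNHILL
        trials.append(
            Trial(
                trial_id=trial_id,
                block_id=block.block_id,
                tilt=block.tilt,
                direction=direction,
                t_start=float(t_entry),
                t_end=float(t_exit),
                duration=duration,
                mean_speed=g.roi_long_cm / duration if complete else float("nan"),
                included=complete,
                reason=None if complete else "incomplete",
            )
        )
        trial_id += 1
        origin = z
        t_entry = None
    return trial_id


def apply_trial_filters(trials: list[Trial],
                        max_duration_s: float = MAX_TRIAL_DURATION_S) -> list[Trial]:
    """Mark completed trials slower than the speed criterion as excluded.

    Idempotent: trials already excluded keep their original reason.
    """
    out = []
    for tr in trials:
        if tr.reason == "incomplete":
            out.append(tr)
        elif tr.duration > max_duration_s:
            out.append(replace(tr, included=False, reason="slow"))
        else:
            out.append(replace(tr, included=True, reason=None))
    return out


def trials_for_condition(trials: list[Trial], condition: Condition,
                         included_only: bool = True) -> list[Trial]:
    return [
        tr for tr in trials
        if tr.condition == condition and (tr.included or not included_only)
    ]


def occupied_extent(occupancy) -> int:
    """Number of grid bins with at least 100 ms of dwell (behavioural spread)."""
    return int(np.count_nonzero(occupancy.visited))
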
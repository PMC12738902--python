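"""Virtual-line crossing counter and transplant-rate computation.

A fixed horizontal segment A0--B0 at height ``y0`` acts as a gate. A tracked
identity is tallied exactly once, for the class it carries at that moment,
when its box center moves from above the line (y < y0) to below it
(y > y0) while its center x lies within [xA0, xB0]. Tying the tally to the
crossing *event* rather than to identity creation is what makes the count
robust to the identity churn a tracker exhibits when targets enter the view.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .formats import TransplantState


@dataclass(frozen=True)
class CountingLine:
    """Horizontal gate with endpoints (xA0, y0) and (xB0, y0)."""

    xA0: float
    xB0: float
    y0: float

    def __post_init__(self) -> None:
        if not self.xA0 < self.xB0:
            raise ValueError(f"need xA0 < xB0, got {self.xA0} >= {self.xB0}")


class Side(enum.Enum):
    ABOVE = "above"
    BELOW = "below"
    UNSEEN = "unseen"


@dataclass
class CountReport:
    """Cumulative per-state tallies; rates are the per-state fractions."""

    counts: dict[TransplantState, int] = field(
        default_factory=lambda: {s: 0 for s in TransplantState}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def rates(self) -> dict[TransplantState, float] | None:
        return compute_rates(self.counts)


def compute_rates(
    counts: dict[TransplantState, int],
) -> dict[TransplantState, float] | None:
    """Per-state fraction of the total count; ``None`` when nothing is counted."""
    total = sum(counts.values())
    if total == 0:
        return None
    return {s: counts.get(s, 0) / total for s in TransplantState}


@dataclass
class CrossingLedger:
    """Per-identity crossing memory: last side seen and whether already counted."""

    line: CountingLine
    last_side: dict[int, Side] = field(default_factory=dict)
    counted: dict[int, TransplantState] = field(default_factory=dict)
    report: CountReport = field(default_factory=CountReport)

    def update(
        self, tracks_at_frame: list[tuple[int, tuple[float, float], TransplantState]]
    ) -> CountReport:
        """Advance one frame; each item is (track_id, (cx, cy), state_label).

        Returns the cumulative report (monotone non-decreasing over frames).
        An identity first observed below the line is remembered as below and
        can therefore never trigger the above-to-below event.
        """
        for track_id, (cx, cy), state in tracks_at_frame:
            side = Side.ABOVE if cy < self.line.y0 else Side.BELOW
            prev = self.last_side.get(track_id, Side.UNSEEN)
            if (
                track_id not in self.counted
                and prev is Side.ABOVE
                and side is Side.BELOW
                and self.line.xA0 <= cx <= self.line.xB0
            ):
                self.counted[track_id] = state
                self.report.counts[state] += 1
            self.last_side[track_id] = side
        return self.report


def update_counter(
    ledger: CrossingLedger,
    line: CountingLine,
    tracks_at_frame: list[tuple[int, tuple[float, float], TransplantState]],
) -> tuple[CrossingLedger, CountReport]:
    """Functional wrapper over :meth:`CrossingLedger.update`."""
    if ledger.line != line:
        raise ValueError("ledger was built for a different counting line")
    report = ledger.update(tracks_at_frame)
    return ledger, report


def default_line(frame_width: int, frame_height: int) -> CountingLine:
    """Full-width gate at 60% of the frame height."""
    return CountingLine(0.0, float(frame_width), 0.6 * frame_height)
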
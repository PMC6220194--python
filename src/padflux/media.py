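"""Media schedule: piecewise-constant culture conditions with switching transients."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class MediaSchedule:
    """Ordered media conditions over an experiment.

    ``segments`` is an ordered list of ``(start_time_s, condition_label)`` with
    strictly increasing start times, the first at 0.  ``switch_duration`` is the
    length of the transient when perfusion switches between media (~40 s on the
    device); downstream analyses discard recording windows overlapping a switch
    and the simulator ramps growth rates linearly across it.
    """

    segments: list[tuple[float, str]] = field(default_factory=lambda: [(0.0, "YPD")])
    switch_duration: float = 40.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("media schedule needs at least one segment")
        starts = [float(s) for s, _ in self.segments]
        if starts[0] != 0.0:
            raise ValueError("first media segment must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("media segment start times must be strictly increasing")
        if self.switch_duration < 0:
            raise ValueError("switch_duration must be >= 0")
        self.segments = [(float(s), str(c)) for s, c in self.segments]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: list[str] = []
        for _, c in self.segments:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def switch_times(self) -> list[float]:
        return [s for s, _ in self.segments[1:]]

    def condition_at(self, t: float) -> str:
        label = self.segments[0][1]
        for s, c in self.segments:
            if t >= s:
                label = c
            else:
                break
        return label

    def intervals(self, duration: float) -> list[tuple[float, float, str]]:
        """``(start, end, label)`` triples covering ``[0, duration)``."""
        out = []
        for i, (s, c) in enumerate(self.segments):
            if s >= duration:
                break
            e = self.segments[i + 1][0] if i + 1 < len(self.segments) else duration
            out.append((s, min(e, duration), c))
        return out
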
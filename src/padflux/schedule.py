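"""Round-robin multiplexing schedule for a single shared impedance analyzer.

The device routes one impedance spectroscope across the electrode pairs of up
to 15 analysis units; each unit gets one recording window per cycle.  Windows
are strictly sequential — the analyzer cannot record two units at once — so
the schedule's concrete windows are non-overlapping by construction.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RecordingWindow:
    unit_id: str
    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class MultiplexSchedule:
    """One analyzer cycle: ordered ``(unit_id, window_length_s)`` entries.

    ``switching_overhead`` is dead time (s) spent re-routing the analyzer
    after each entry; it defaults to 0 but is a first-class parameter.
    """

    entries: list[tuple[str, float]]
    switching_overhead: float = 0.0

    def __post_init__(self) -> None:
        if self.switching_overhead < 0:
            raise ValueError("switching_overhead must be >= 0")
        seen: set[str] = set()
        cleaned = []
        for unit_id, w in self.entries:
            w = float(w)
            if w <= 0:
                raise ValueError(f"window length for unit {unit_id!r} must be > 0, got {w}")
            if unit_id in seen:
                raise ValueError(f"unit {unit_id!r} appears more than once per cycle")
            seen.add(unit_id)
            cleaned.append((str(unit_id), w))
        self.entries = cleaned

    @property
    def cycle_time(self) -> float:
        """Duration of one full cycle: windows plus per-entry switching overhead."""
        return sum(w for _, w in self.entries) + self.switching_overhead * len(self.entries)

    def window_length(self, unit_id: str) -> float:
        for uid, w in self.entries:
            if uid == unit_id:
                return w
        raise KeyError(unit_id)

    def windows(self, duration: float, start: float = 0.0) -> list[RecordingWindow]:
        """Expand the cycle into concrete windows covering ``[start, start+duration)``.

        Only windows that fit entirely inside the span are produced; a cycle
        truncated by the end of the experiment contributes its complete
        windows only.
        """
        if not self.entries:
            return []
        if duration <= 0:
            raise ValueError("duration must be > 0")
        out: list[RecordingWindow] = []
        t = start
        end = start + duration
        while True:
            for unit_id, w in self.entries:
                if t + w > end + 1e-9:
                    return out
                out.append(RecordingWindow(unit_id, t, t + w))
                t += w + self.switching_overhead
            if not out:  # pragma: no cover - guarded by entry validation
                return out

    def windows_for_unit(self, unit_id: str, duration: float, start: float = 0.0) -> list[RecordingWindow]:
        return [w for w in self.windows(duration, start) if w.unit_id == unit_id]


def validate_nonoverlapping(windows: list[RecordingWindow]) -> None:
    """Raise if any two windows overlap in time (single shared analyzer)."""
    ordered = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end - 1e-12:
            raise ValueError(
                f"overlapping recording windows: {a.unit_id} [{a.start}, {a.end}) and "
                f"{b.unit_id} [{b.start}, {b.end})"
            )
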
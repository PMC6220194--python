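"""Normalized peak rates, budding-corrected growth rates, and condition summaries.

The estimator
-------------
For a recording window of length ``w`` (hours) with peak count ``c`` at an
analysis unit holding ``N_bar`` cells (the arithmetic mean of the cell
counts at the start and end of the recording session), the normalized peak
rate is

    peak_rate_norm = c / (N_bar * w)        [events / h / cell]

which is proportional to the per-cell growth rate and independent of colony
size, so units with different numbers of filled pads are directly
comparable.  A fraction BI (the budding index) of passing cells is budded —
mother and bud pass the electrodes as a single object and yield one peak —
so each peak carries on average (1 + BI) cells and the absolute growth rate
is

    growth_rate = peak_rate_norm * (1 + BI)

Per media condition, the estimate is the arithmetic mean of per-window
rates with its standard error (sample SD / sqrt(n), over windows).

:class:`GrowthRateModel` wraps these steps in a model/results pair: build
the model from window counts plus unit metadata (and optionally a media
schedule), call :meth:`~GrowthRateModel.fit`, and read estimates off the
returned :class:`GrowthRateResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detection import WindowCount
from .media import MediaSchedule

__all__ = [
    "AnalysisUnitMeta",
    "PeakRateSeries",
    "GrowthRateEstimate",
    "GrowthRateModel",
    "GrowthRateResults",
    "normalize_peak_rate",
    "correct_for_budding",
    "segment_by_condition",
    "condition_summary",
    "relative_change",
]

_SECONDS_PER_HOUR = 3600.0


@dataclass
class AnalysisUnitMeta:
    """Metadata of one analysis unit needed for normalization.

    ``cell_count_start`` / ``cell_count_end`` are the averaged microscopy
    cell counts under the unit's pads at the beginning and end of the
    impedance recording session; their arithmetic mean normalizes the peak
    counts.  Each analysis unit has four clamping pads, of which
    ``pads_filled`` hold colonies.
    """

    unit_id: str
    chamber_id: str = ""
    pads_filled: int = 4
    cell_count_start: float = 0.0
    cell_count_end: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= int(self.pads_filled) <= 4:
            raise ValueError("pads_filled must be in 0..4 (four pads per analysis unit)")
        if self.cell_count_start < 0 or self.cell_count_end < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def mean_cell_count(self) -> float:
        return 0.5 * (self.cell_count_start + self.cell_count_end)


@dataclass
class PeakRateSeries:
    """Per-window normalized peak rates of one unit (one condition, or unsplit)."""

    unit_id: str
    condition: str | None
    window_starts: np.ndarray
    window_lengths: np.ndarray
    rates: np.ndarray  # events per hour per cell

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.window_lengths = np.asarray(self.window_lengths, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if not (self.window_starts.size == self.window_lengths.size == self.rates.size):
            raise ValueError("window_starts, window_lengths and rates must align")
        if np.any(self.rates < 0):
            raise ValueError("peak rates must be >= 0")

    def __len__(self) -> int:
        return self.rates.size


@dataclass
class GrowthRateEstimate:
    """Mean +/- SEM of the normalized peak rate (and budding-corrected growth rate)."""

    unit_id: str
    condition: str | None
    mean_peak_rate: float  # /h
    sem_peak_rate: float  # /h
    n_windows: int
    budding_index: float
    growth_rate: float  # /h, = mean_peak_rate * (1 + budding_index)
    sem_growth_rate: float  # /h
    sem_defined: bool = True  # False when n_windows == 1


def normalize_peak_rate(
    counts: Sequence[WindowCount], meta: AnalysisUnitMeta, condition: str | None = None
) -> PeakRateSeries:
    """Convert window counts to normalized peak rates (events/h/cell).

    Each window's count is divided by the unit's mean cell count
    ``(cell_count_start + cell_count_end)/2`` and by the window duration in
    hours.  Windows may have different lengths; each is normalized by its
    own.
    """
    n_bar = meta.mean_cell_count
    if n_bar <= 0:
        raise ValueError(
            f"unit {meta.unit_id!r}: mean cell count is 0 — unit not normalizable"
        )
    starts = np.array([c.start for c in counts], dtype=float)
    lengths = np.array([c.length for c in counts], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("window lengths must be > 0")
    values = np.array([c.count for c in counts], dtype=float)
    rates = values / (n_bar * lengths / _SECONDS_PER_HOUR)
    return PeakRateSeries(meta.unit_id, condition, starts, lengths, rates)


def correct_for_budding(rate: float, budding_index: float) -> float:
    """Budding-corrected growth rate: ``rate * (1 + budding_index)``.

    A budded passage carries two cells (mother + bud) but yields one peak,
    so the expected number of cells per peak is 1 + BI.
    """
    if not 0.0 <= budding_index <= 1.0:
        raise ValueError("budding_index must be in [0, 1]")
    return rate * (1.0 + budding_index)


def segment_by_condition(
    series: PeakRateSeries, media: MediaSchedule, buffer: float | None = None
) -> list[PeakRateSeries]:
    """Split a rate series into one series per media-condition segment.

    A window is assigned to the condition whose media segment fully contains
    it; windows overlapping a switch time +/- ``buffer`` (default: the
    schedule's switch duration) are discarded.  Consecutive media segments
    with the same label contribute to the same output series.
    """
    if buffer is None:
        buffer = media.switch_duration
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    horizon = float(np.max(series.window_starts + series.window_lengths)) if len(series) else 0.0
    intervals = media.intervals(max(horizon, media.segments[-1][0] + 1.0))
    switch_times = media.switch_times

    assigned: dict[str, list[int]] = {}
    order: list[str] = []
    for i in range(len(series)):
        ws = series.window_starts[i]
        we = ws + series.window_lengths[i]
        if any(ws < s + buffer and we > s - buffer for s in switch_times):
            continue
        for s, e, label in intervals:
            if ws >= s and we <= e:
                if label not in assigned:
                    assigned[label] = []
                    order.append(label)
                assigned[label].append(i)
                break
    out = []
    for label in order:
        ix = np.asarray(assigned[label], dtype=int)
        out.append(
            PeakRateSeries(
                series.unit_id,
                label,
                series.window_starts[ix],
                series.window_lengths[ix],
                series.rates[ix],
            )
        )
    if not out:
        warnings.warn(
            f"unit {series.unit_id!r}: no window fully inside any condition segment "
            "(all windows fall in switch buffer zones)",
            stacklevel=2,
        )
    return out


def condition_summary(series: PeakRateSeries, budding_index: float) -> GrowthRateEstimate:
    """Mean and SEM of a rate series, with budding-corrected growth rate.

    SEM uses the sample (n-1) standard deviation over windows.  With a
    single window the SEM is reported as 0 and flagged undefined.
    """
    if len(series) == 0:
        raise ValueError(f"unit {series.unit_id!r}: empty series — no windows to summarize")
    if not 0.0 <= budding_index <= 1.0:
        raise ValueError("budding_index must be in [0, 1]")
    n = len(series)
    mean = float(np.mean(series.rates))
    if n > 1:
        sem = float(np.std(series.rates, ddof=1) / math.sqrt(n))
        sem_defined = True
    else:
        sem = 0.0
        sem_defined = False
    factor = 1.0 + budding_index
    return GrowthRateEstimate(
        unit_id=series.unit_id,
        condition=series.condition,
        mean_peak_rate=mean,
        sem_peak_rate=sem,
        n_windows=n,
        budding_index=budding_index,
        growth_rate=mean * factor,
        sem_growth_rate=sem * factor,
        sem_defined=sem_defined,
    )


def relative_change(rate_reference: float, rate_other: float) -> float:
    """Percent change of ``rate_other`` relative to ``rate_reference``.

    The reference is the pre-switch (slower, e.g. calcium) condition:
    ``100 * (other - reference) / reference``.
    """
    if rate_reference <= 0:
        raise ValueError("reference rate must be > 0")
    return 100.0 * (rate_other - rate_reference) / rate_reference


class GrowthRateModel:
    """Growth-rate estimation from windowed peak counts.

    Parameters
    ----------
    counts : sequence of WindowCount
        Windowed peak counts for one or more analysis units.
    meta : mapping or sequence of AnalysisUnitMeta
        Unit metadata (cell counts for normalization), keyed by unit id.
    media : MediaSchedule, optional
        When given, windows are segmented by media condition (windows
        overlapping a switch +/- ``switch_buffer`` are discarded).
    budding_index : float
        Fraction of budded passages; scales peak rate to growth rate.
    switch_buffer : float, optional
        Guard band around media switches in seconds; defaults to the
        schedule's switch duration.

    Examples
    --------
    >>> model = GrowthRateModel(counts, meta, media=media, budding_index=0.6)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        counts: Sequence[WindowCount],
        meta: Mapping[str, AnalysisUnitMeta] | Sequence[AnalysisUnitMeta],
        media: MediaSchedule | None = None,
        budding_index: float = 0.6,
        switch_buffer: float | None = None,
    ) -> None:
        if not 0.0 <= budding_index <= 1.0:
            raise ValueError("budding_index must be in [0, 1]")
        if not isinstance(meta, Mapping):
            meta = {m.unit_id: m for m in meta}
        self.counts = list(counts)
        self.meta = dict(meta)
        self.media = media
        self.budding_index = budding_index
        self.switch_buffer = switch_buffer
        missing = {c.unit_id for c in self.counts} - set(self.meta)
        if missing:
            raise ValueError(f"window counts for units without metadata: {sorted(missing)}")

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        meta: pd.DataFrame,
        media: MediaSchedule | None = None,
        budding_index: float = 0.6,
        switch_buffer: float | None = None,
    ) -> "GrowthRateModel":
        """Build from tabular inputs.

        ``counts`` needs columns ``unit_id, window_start_s, window_length_s,
        count``; ``meta`` needs ``unit_id, chamber_id, pads_filled,
        cell_count_start, cell_count_end``.
        """
        wcs = [
            WindowCount(str(r.unit_id), float(r.window_start_s), float(r.window_length_s), int(r.count))
            for r in counts.itertuples()
        ]
        metas = {
            str(r.unit_id): AnalysisUnitMeta(
                unit_id=str(r.unit_id),
                chamber_id=str(getattr(r, "chamber_id", "")),
                pads_filled=int(getattr(r, "pads_filled", 4)),
                cell_count_start=float(r.cell_count_start),
                cell_count_end=float(r.cell_count_end),
            )
            for r in meta.itertuples()
        }
        return cls(wcs, metas, media=media, budding_index=budding_index, switch_buffer=switch_buffer)

    def fit(self) -> "GrowthRateResults":
        """Estimate per-unit (and per-condition) growth rates."""
        by_unit: dict[str, list[WindowCount]] = {}
        for c in self.counts:
            by_unit.setdefault(c.unit_id, []).append(c)
        series_list: list[PeakRateSeries] = []
        estimates: list[GrowthRateEstimate] = []
        for unit_id in sorted(by_unit):
            wcs = sorted(by_unit[unit_id], key=lambda c: c.start)
            series = normalize_peak_rate(wcs, self.meta[unit_id])
            if self.media is not None and len(self.media.segments) > 1:
                parts = segment_by_condition(series, self.media, self.switch_buffer)
            else:
                label = self.media.segments[0][1] if self.media is not None else None
                parts = [replace(series, condition=label)]
            for part in parts:
                if len(part) == 0:
                    continue
                series_list.append(part)
                estimates.append(condition_summary(part, self.budding_index))
        return GrowthRateResults(self, estimates, series_list)


class GrowthRateResults:
    """Fitted growth-rate estimates with uncertainties and diagnostics."""

    def __init__(
        self,
        model: GrowthRateModel,
        estimates: list[GrowthRateEstimate],
        series: list[PeakRateSeries],
    ) -> None:
        self.model = model
        self.estimates = estimates
        self.series = series

    def to_frame(self) -> pd.DataFrame:
        """Estimates as a DataFrame (rates in /h)."""
        return pd.DataFrame(
            {
                "unit_id": [e.unit_id for e in self.estimates],
                "condition": [e.condition if e.condition is not None else "all" for e in self.estimates],
                "mean_peak_rate_per_h": [e.mean_peak_rate for e in self.estimates],
                "sem_peak_rate_per_h": [e.sem_peak_rate for e in self.estimates],
                "n_windows": [e.n_windows for e in self.estimates],
                "budding_index": [e.budding_index for e in self.estimates],
                "growth_rate_per_h": [e.growth_rate for e in self.estimates],
                "sem_growth_rate_per_h": [e.sem_growth_rate for e in self.estimates],
            }
        )

    def get(self, unit_id: str, condition: str | None = None) -> GrowthRateEstimate:
        """Estimate for one unit (and condition, when segmented)."""
        for e in self.estimates:
            if e.unit_id == unit_id and (condition is None or e.condition == condition):
                return e
        raise KeyError((unit_id, condition))

    def relative_changes(self) -> pd.DataFrame:
        """Relative growth-rate change between adjacent conditions, per unit.

        For each unit and each pair of consecutive conditions encountered in
        time, the change is reported relative to the slower condition of the
        pair (the convention that makes a recovery from a growth-inhibiting
        medium a positive change).
        """
        rows = []
        by_unit: dict[str, list[GrowthRateEstimate]] = {}
        for e in self.estimates:
            by_unit.setdefault(e.unit_id, []).append(e)
        for unit_id, ests in by_unit.items():
            for a, b in zip(ests, ests[1:]):
                ref, other = (a, b) if a.mean_peak_rate <= b.mean_peak_rate else (b, a)
                if ref.mean_peak_rate <= 0:
                    continue
                rows.append(
                    {
                        "unit_id": unit_id,
                        "reference_condition": ref.condition,
                        "other_condition": other.condition,
                        "reference_rate_per_h": ref.mean_peak_rate,
                        "other_rate_per_h": other.mean_peak_rate,
                        "relative_change_percent": relative_change(
                            ref.mean_peak_rate, other.mean_peak_rate
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Growth-rate estimates (impedance peak rates)",
            "=" * 76,
            f"units: {len({e.unit_id for e in self.estimates})}    "
            f"budding index: {self.model.budding_index:.2f}    "
            f"correction factor: {1 + self.model.budding_index:.2f}",
            "-" * 76,
            f"{'unit':<10}{'condition':<12}{'peak rate /h':>14}{'SEM':>10}"
            f"{'n':>6}{'growth /h':>12}{'SEM':>10}",
            "-" * 76,
        ]
        for e in self.estimates:
            sem_txt = f"{e.sem_peak_rate:.4f}" if e.sem_defined else "undef(n=1)"
            semg_txt = f"{e.sem_growth_rate:.4f}" if e.sem_defined else "undef(n=1)"
            lines.append(
                f"{e.unit_id:<10}{(e.condition or 'all'):<12}{e.mean_peak_rate:>14.4f}"
                f"{sem_txt:>10}{e.n_windows:>6d}{e.growth_rate:>12.4f}{semg_txt:>10}"
            )
        changes = self.relative_changes()
        if len(changes):
            lines += ["-" * 76, "relative changes (reference = slower condition):"]
            for r in changes.itertuples():
                lines.append(
                    f"  {r.unit_id}: {r.reference_condition} -> {r.other_condition}: "
                    f"{r.relative_change_percent:+.0f}%"
                )
        lines.append("=" * 76)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter per-window normalized peak rates vs time, mean per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for series in self.series:
            t_h = series.window_starts / 3600.0
            label = f"{series.unit_id}" + (f" ({series.condition})" if series.condition else "")
            pts = ax.plot(t_h, series.rates, "o", ms=3, alpha=0.6, label=label)
            est = next(
                e
                for e in self.estimates
                if e.unit_id == series.unit_id and e.condition == series.condition
            )
            ax.hlines(
                est.mean_peak_rate,
                t_h.min(),
                (series.window_starts[-1] + series.window_lengths[-1]) / 3600.0,
                colors=pts[0].get_color(),
            )
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalized peak rate (/h)")
        ax.legend(fontsize="small")
        return ax
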
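"""Bandpass filtering, threshold peak extraction, and windowed peak counting.

The raw phase trace carries slow baseline drift plus millidegree-scale
transients when cells pass the electrodes.  Detection follows the device's
analysis chain: a zero-phase 0.1–30 Hz Butterworth bandpass removes drift
and out-of-band noise, then every local maximum of the filtered signal above
an amplitude threshold is a cell-passage event.  Thresholds depend on medium
and stimulation frequency; the printed operating ranges are 2e-3–6e-3
degrees at 1.5 MHz and 0.5e-3–0.8e-3 degrees at 1.12 MHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .traces import PhaseTrace

__all__ = [
    "DetectionConfig",
    "PeakEvent",
    "WindowCount",
    "default_threshold",
    "bandpass_filter",
    "detect_peaks",
    "count_peaks_in_windows",
]

#: Default detection thresholds (degrees) by stimulation frequency: the
#: midpoint of each printed operating range.
DEFAULT_THRESHOLDS = {1.5e6: 4.0e-3, 1.12e6: 0.65e-3}

#: Minimum trace duration for filtering, as a multiple of 1/band_low.
_MIN_DURATION_FACTOR = 3.0


def default_threshold(frequency: float) -> float:
    """Midpoint-of-range default threshold for a stimulation frequency."""
    for f, thr in DEFAULT_THRESHOLDS.items():
        if math.isclose(frequency, f, rel_tol=1e-3):
            return thr
    raise KeyError(
        f"no default threshold for frequency {frequency:g} Hz; supply one explicitly"
    )


@dataclass
class DetectionConfig:
    """Peak-detection parameters.

    ``band_low``/``band_high`` bound the bandpass in Hz; ``threshold`` is the
    minimum filtered-signal amplitude (degrees) for a peak; maxima closer
    than ``min_separation`` seconds are merged, keeping the larger.
    """

    band_low: float = 0.1
    band_high: float = 30.0
    threshold: float = 4.0e-3
    min_separation: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")

    @property
    def warmup(self) -> float:
        """Edge margin (s) excluded from detection: one high-pass time constant."""
        return 1.0 / self.band_low


@dataclass(frozen=True)
class PeakEvent:
    """One detected cell passage: local-maximum time, filtered height, FWHM."""

    unit_id: str
    time: float
    amplitude: float
    width: float


@dataclass(frozen=True)
class WindowCount:
    """Peak count within one recording window of one unit."""

    unit_id: str
    start: float
    length: float
    count: int


def _design_sos(band_low: float, band_high: float, fs: float) -> np.ndarray:
    if band_high >= fs / 2:
        raise ValueError(
            f"band_high {band_high:g} Hz must be below Nyquist ({fs / 2:g} Hz)"
        )
    return signal.butter(2, [band_low, band_high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    trace: PhaseTrace, band_low: float = 0.1, band_high: float = 30.0
) -> PhaseTrace:
    """Zero-phase Butterworth bandpass of a phase trace.

    A 4th-order bandpass (2 poles per skirt) applied forward-backward
    (``sosfiltfilt``), so peak times are not shifted.  Output has the same
    length and timebase as the input.
    """
    if not 0 < band_low < band_high:
        raise ValueError("need 0 < band_low < band_high")
    min_dur = _MIN_DURATION_FACTOR / band_low
    if trace.duration < min_dur:
        raise ValueError(
            f"trace of {trace.duration:g} s is shorter than the filter warm-up; "
            f"need at least {min_dur:g} s (= {_MIN_DURATION_FACTOR:g}/band_low)"
        )
    sos = _design_sos(band_low, band_high, trace.sampling_rate)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return PhaseTrace(
        unit_id=trace.unit_id,
        sampling_rate=trace.sampling_rate,
        samples=filtered,
        start_time=trace.start_time,
        frequency=trace.frequency,
        segment_index=trace.segment_index,
    )


def bandpass_frequency_response(
    band_low: float, band_high: float, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Magnitude response of the *zero-phase* filter at ``freqs`` (Hz).

    Forward-backward application squares the single-pass magnitude.
    """
    sos = _design_sos(band_low, band_high, fs)
    _, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=fs)
    return np.abs(h) ** 2


def detect_peaks(
    trace: PhaseTrace, config: DetectionConfig, prefiltered: bool = False
) -> list[PeakEvent]:
    """Extract cell-passage peaks from a phase trace.

    Applies the bandpass internally unless ``prefiltered``.  Returns every
    local maximum of the filtered signal exceeding ``config.threshold``;
    maxima closer than ``config.min_separation`` are merged keeping the
    larger.  Peaks inside the edge warm-up margin (1/band_low seconds at
    each end of the segment) are discarded to avoid filter transients.
    Events are sorted by time with amplitude (filtered height) and width
    (span above half-amplitude) populated.
    """
    if len(trace) == 0:
        return []
    filtered = trace if prefiltered else bandpass_filter(trace, config.band_low, config.band_high)
    x = filtered.samples
    fs = filtered.sampling_rate
    distance = max(1, int(round(config.min_separation * fs)))
    idx, _ = signal.find_peaks(x, height=config.threshold, distance=distance)
    if idx.size == 0:
        return []
    widths_samples = signal.peak_widths(x, idx, rel_height=0.5)[0]
    margin = config.warmup
    events: list[PeakEvent] = []
    for i, w in zip(idx, widths_samples):
        t_rel = i / fs
        if t_rel < margin or t_rel > filtered.duration - margin:
            continue
        events.append(
            PeakEvent(
                unit_id=trace.unit_id,
                time=filtered.start_time + t_rel,
                amplitude=float(x[i]),
                width=float(w / fs),
            )
        )
    return events


def count_peaks_in_windows(
    events: list[PeakEvent] | np.ndarray,
    window_length: float,
    segment: tuple[float, float],
    unit_id: str | None = None,
) -> list[WindowCount]:
    """Count events in consecutive fixed-length windows over a segment.

    The segment ``[start, end)`` is partitioned into half-open windows
    ``[start + i*w, start + (i+1)*w)``; a trailing partial window is
    discarded.  An event exactly on a boundary belongs to the later window.
    """
    start, end = segment
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    if end <= start:
        raise ValueError("segment end must exceed start")
    if isinstance(events, np.ndarray):
        times = np.asarray(events, dtype=float)
        uid = unit_id or "unit"
    else:
        times = np.array([e.time for e in events], dtype=float)
        uid = unit_id or (events[0].unit_id if events else "unit")
    n_windows = int(math.floor((end - start) / window_length + 1e-9))
    counts = np.zeros(n_windows, dtype=int)
    if times.size and n_windows:
        rel = (times - start) / window_length
        bins = np.floor(rel + 1e-12).astype(int)
        valid = (bins >= 0) & (bins < n_windows) & (times >= start)
        np.add.at(counts, bins[valid], 1)
    return [
        WindowCount(uid, start + i * window_length, window_length, int(c))
        for i, c in enumerate(counts)
    ]
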
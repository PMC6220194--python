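"""Phase-signal trace container and plain-text trace file I/O.

A :class:`PhaseTrace` holds the uniformly sampled impedance phase signal
(in degrees) recorded at one analysis unit's electrode pair at a single
stimulation frequency.  Gaps produced by round-robin multiplexing are not
represented inside a trace: each contiguous recording segment is its own
``PhaseTrace`` object (and its own file on disk).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Upper edge of the detection band (Hz); sampling must satisfy Nyquist for it.
MAX_BAND_HZ = 30.0


@dataclass
class PhaseTrace:
    """Uniformly sampled phase signal for one analysis unit.

    Parameters
    ----------
    unit_id : str
        Identifier of the analysis unit the trace was recorded from.
    sampling_rate : float
        Sampling rate in Hz.  Must exceed twice the 30 Hz detection band.
    samples : ndarray
        Phase values in degrees.
    start_time : float
        Time of the first sample, in seconds from experiment start.
    frequency : float
        Stimulation frequency in Hz (1.12 MHz or 1.5 MHz on the device).
    """

    unit_id: str
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0
    frequency: float = 1.5e6
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not math.isfinite(self.sampling_rate) or self.sampling_rate <= 2 * MAX_BAND_HZ:
            raise ValueError(
                f"sampling_rate must exceed {2 * MAX_BAND_HZ:g} Hz "
                f"(Nyquist above the 30 Hz band), got {self.sampling_rate!r}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from experiment start."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def crop(self, start: float, end: float, segment_index: int | None = None) -> "PhaseTrace":
        """Return the sub-trace with sample times in the half-open ``[start, end)``."""
        if end <= start:
            raise ValueError("crop window must have end > start")
        fs = self.sampling_rate
        i0 = max(0, math.ceil((start - self.start_time) * fs - 1e-9))
        i1 = min(self.samples.size, math.ceil((end - self.start_time) * fs - 1e-9))
        i1 = max(i0, i1)
        return replace(
            self,
            samples=self.samples[i0:i1].copy(),
            start_time=self.start_time + i0 / fs,
            segment_index=self.segment_index if segment_index is None else segment_index,
        )


def trace_filename(unit_id: str, segment_index: int) -> str:
    """Canonical file name carrying unit id and segment index."""
    return f"trace_{unit_id}_seg{segment_index:03d}.tsv"


_FNAME_RE = re.compile(r"trace_(?P<unit>.+)_seg(?P<seg>\d+)\.tsv$")


def write_trace(trace: PhaseTrace, path: str | Path) -> Path:
    """Write a trace as tab-delimited text: metadata comments, header, two columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unit_id: {trace.unit_id}\n")
        fh.write(f"# frequency_hz: {trace.frequency:.10g}\n")
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate:.10g}\n")
        fh.write(f"# segment_index: {trace.segment_index}\n")
        fh.write("time_s\tphase_deg\n")
        t = trace.times
        for ti, xi in zip(t, trace.samples):
            fh.write(f"{ti:.10g}\t{xi:.10g}\n")
    return path


def read_trace(path: str | Path) -> PhaseTrace:
    """Read a trace file written by :func:`write_trace`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"time_s", "phase_deg"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s and phase_deg")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: trace needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: non-uniform sampling; gaps must be separate segments")
    fs = float(meta.get("sampling_rate_hz", 1.0 / dt[0]))
    m = _FNAME_RE.search(path.name)
    unit_id = meta.get("unit_id") or (m.group("unit") if m else path.stem)
    seg = int(meta.get("segment_index", m.group("seg") if m else 0))
    return PhaseTrace(
        unit_id=unit_id,
        sampling_rate=fs,
        samples=df["phase_deg"].to_numpy(float),
        start_time=float(t[0]),
        frequency=float(meta.get("frequency_hz", 1.5e6)),
        segment_index=seg,
    )
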
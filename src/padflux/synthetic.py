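"""Digital twin of the micro-chemostat impedance readout.

Generates colony trajectories, cell-passage event streams and raw phase
traces with known ground truth, so the whole analysis chain (filtering, peak
detection, rate normalisation, condition comparison) can be exercised and
validated without any experimental data.

The generative model
--------------------
Cells clamped under a PDMS pad grow as a 2D monolayer until the pad area is
full (``fill_time``).  From then on the colony size is constant and every
division pushes one cell out of the colony and over the sensing electrodes,
so escapes form a Poisson process with rate

    lambda = growth_rate_per_cell * pad_capacity        [events/h]

where ``growth_rate_per_cell`` is the per-cell *escape/peak* rate — the
quantity the normalized peak rate estimates.  A fraction ``budding_index``
of passing cells is budded; mother and bud pass as one object and yield a
single peak, which is why a (1 + BI) correction relates peak rate to the
absolute growth rate downstream.

Each passage produces a transient unimodal (Gaussian) bump in the phase
signal, of order 1e-3 degrees, superposed on slow baseline drift and white
Gaussian noise.  A round-robin multiplexing schedule then crops each unit's
continuous trace into the recorded segments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .media import MediaSchedule
from .schedule import MultiplexSchedule, validate_nonoverlapping
from .traces import PhaseTrace

__all__ = [
    "ColonyParams",
    "NoiseModel",
    "EventStream",
    "ColonySimulation",
    "SyntheticExperiment",
    "simulate_colony",
    "synthesize_trace",
    "apply_multiplex_schedule",
]

_SECONDS_PER_HOUR = 3600.0
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass
class ColonyParams:
    """Parameters of one clamped colony.

    Parameters
    ----------
    growth_rate_per_cell : float
        Per-cell escape/peak rate in events per hour per cell.  This is the
        quantity the normalized peak rate estimates; the biological division
        rate is ``(1 + budding_index)`` times larger.
    pad_capacity : int
        Colony size (cells) once the pad area is full.
    initial_cells : int
        Cells clamped at loading; ``initial_cells == pad_capacity`` models a
        pre-filled pad (events start immediately).
    budding_index : float
        Fraction of passing cells that are budded, in [0, 1].
    fill_model : str
        ``"deterministic-exponential"`` (default): N(t) = min(N0 e^{rt}, K).
        ``"stochastic-birth"``: a Yule birth process with per-cell rate r.
    condition_rates : mapping, optional
        Per-condition per-cell escape rates (events/h), keyed by media
        condition label.  With a :class:`~padflux.media.MediaSchedule` the
        rate follows the active condition, ramping linearly over the switch
        duration.  Labels not listed fall back to ``growth_rate_per_cell``.
    """

    growth_rate_per_cell: float
    pad_capacity: int = 400
    initial_cells: int | None = None
    budding_index: float = 0.6
    fill_model: str = "deterministic-exponential"
    condition_rates: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        self.growth_rate_per_cell = _check_finite("growth_rate_per_cell", self.growth_rate_per_cell)
        if self.growth_rate_per_cell < 0:
            raise ValueError("growth_rate_per_cell must be >= 0")
        self.pad_capacity = int(self.pad_capacity)
        if self.pad_capacity < 1:
            raise ValueError("pad_capacity must be >= 1")
        if self.initial_cells is None:
            self.initial_cells = self.pad_capacity
        self.initial_cells = int(self.initial_cells)
        if not 0 <= self.initial_cells <= self.pad_capacity:
            raise ValueError("initial_cells must satisfy 0 <= initial_cells <= pad_capacity")
        self.budding_index = _check_finite("budding_index", self.budding_index)
        if not 0.0 <= self.budding_index <= 1.0:
            raise ValueError("budding_index must be in [0, 1]")
        if self.fill_model not in ("deterministic-exponential", "stochastic-birth"):
            raise ValueError(f"unknown fill_model {self.fill_model!r}")
        if self.condition_rates is not None:
            for label, r in self.condition_rates.items():
                if not math.isfinite(r) or r < 0:
                    raise ValueError(f"condition rate for {label!r} must be finite and >= 0")

    def per_cell_rate_fn(self, media: MediaSchedule | None) -> Callable[[float], float]:
        """Per-cell escape rate (events/h) as a function of time.

        Piecewise constant over media conditions, with a linear ramp of
        ``media.switch_duration`` seconds starting at each switch.
        """
        base = self.growth_rate_per_cell
        if media is None or not self.condition_rates:
            return lambda t: base

        rates = dict(self.condition_rates)
        seg_starts = [s for s, _ in media.segments]
        seg_rates = [rates.get(c, base) for _, c in media.segments]
        ramp = media.switch_duration

        def rate(t: float) -> float:
            i = 0
            for j, s in enumerate(seg_starts):
                if t >= s:
                    i = j
                else:
                    break
            r_now = seg_rates[i]
            if i > 0 and ramp > 0 and t < seg_starts[i] + ramp:
                r_prev = seg_rates[i - 1]
                frac = (t - seg_starts[i]) / ramp
                return r_prev + (r_now - r_prev) * frac
            return r_now

        return rate


@dataclass
class NoiseModel:
    """Additive signal model of the phase channel.

    All amplitudes in degrees, times in seconds.  The 2e-3–6e-3 degree
    detection-threshold range at 1.5 MHz anchors the peak-amplitude scale;
    the drift period sits far below the 0.1 Hz high-pass corner so the
    bandpass removes it.
    """

    gaussian_sd: float = 5e-4
    drift_amplitude: float = 5e-3
    drift_period: float = 300.0
    peak_amplitude_median: float = 4e-3
    peak_amplitude_log_sd: float = 0.15
    peak_width_mean: float = 0.020
    peak_width_sd: float = 0.002

    def __post_init__(self) -> None:
        for name in (
            "gaussian_sd",
            "drift_amplitude",
            "drift_period",
            "peak_amplitude_median",
            "peak_amplitude_log_sd",
            "peak_width_mean",
            "peak_width_sd",
        ):
            v = _check_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
            setattr(self, name, v)


@dataclass
class EventStream:
    """Cell-passage events of one analysis unit (times strictly increasing)."""

    unit_id: str
    times: np.ndarray
    budded: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.budded = np.asarray(self.budded, dtype=bool)
        if self.times.shape != self.budded.shape:
            raise ValueError("times and budded must have the same length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def in_interval(self, start: float, end: float) -> "EventStream":
        keep = (self.times >= start) & (self.times < end)
        return EventStream(self.unit_id, self.times[keep], self.budded[keep])


@dataclass
class ColonySimulation:
    """Output of :func:`simulate_colony`: fill time, N(t), and the event stream."""

    fill_time: float
    cell_count: Callable[[np.ndarray | float], np.ndarray | float]
    events: EventStream


def simulate_colony(
    params: ColonyParams,
    duration: float,
    seed: int | np.random.SeedSequence,
    unit_id: str = "unit",
    media: MediaSchedule | None = None,
) -> ColonySimulation:
    """Simulate one colony: fill-up, then Poisson cell escapes.

    The colony grows from ``initial_cells`` to ``pad_capacity`` (``fill_time``
    is +inf if it never fills, 0 if pre-filled).  After fill, escape events
    form a Poisson process with rate ``per-cell rate x pad_capacity``; each
    event is independently flagged budded with probability ``budding_index``.
    No events occur before the pad is full.

    Time-varying per-cell rates (media switches) are handled by thinning
    against the maximum rate over the run.
    """
    if not (math.isfinite(duration) and duration > 0):
        raise ValueError("duration must be finite and > 0")
    rng = np.random.default_rng(seed)
    rate_fn = params.per_cell_rate_fn(media)
    r0 = rate_fn(0.0) / _SECONDS_PER_HOUR  # per-cell rate in /s at loading
    K = params.pad_capacity
    N0 = params.initial_cells

    # --- fill phase ---
    if N0 == K:
        fill_time = 0.0
        cell_count = _constant_count(K)
    elif N0 == 0 or r0 <= 0:
        fill_time = math.inf
        cell_count = _constant_count(N0)
    elif params.fill_model == "deterministic-exponential":
        fill_time = math.log(K / N0) / r0
        cell_count = _exponential_count(N0, K, r0, fill_time)
    else:  # stochastic-birth (Yule process, per-cell birth rate from the profile)
        birth_times = []
        t, n = 0.0, N0
        while n < K:
            r = max(rate_fn(t), 0.0) / _SECONDS_PER_HOUR
            if r <= 0:
                t = math.inf
                break
            t += rng.exponential(1.0 / (r * n))
            n += 1
            birth_times.append(t)
        fill_time = t if birth_times or N0 == K else math.inf
        cell_count = _step_count(N0, np.asarray(birth_times))

    # --- post-fill escape events ---
    times: list[float] = []
    if math.isfinite(fill_time) and fill_time < duration:
        lam_max = max(rate_fn(t) for t in _rate_grid(media, fill_time, duration)) * K / _SECONDS_PER_HOUR
        if lam_max > 0:
            t = fill_time
            while True:
                t += rng.exponential(1.0 / lam_max)
                if t >= duration:
                    break
                lam_t = rate_fn(t) * K / _SECONDS_PER_HOUR
                if rng.random() < lam_t / lam_max:
                    times.append(t)
    times_arr = np.asarray(times, dtype=float)
    budded = rng.random(times_arr.size) < params.budding_index
    return ColonySimulation(fill_time, cell_count, EventStream(unit_id, times_arr, budded))


def _rate_grid(media: MediaSchedule | None, start: float, end: float) -> list[float]:
    """Times at which the piecewise-linear rate profile can attain its maximum."""
    pts = [start, end]
    if media is not None:
        for s in [0.0] + media.switch_times:
            for p in (s, s + media.switch_duration):
                if start <= p <= end:
                    pts.append(p)
    return pts


def _constant_count(n: int) -> Callable:
    return lambda t: np.full_like(np.asarray(t, dtype=float), float(n)) if np.ndim(t) else float(n)


def _exponential_count(n0: int, cap: int, r_per_s: float, fill_time: float) -> Callable:
    def count(t):
        t = np.asarray(t, dtype=float)
        return np.minimum(n0 * np.exp(r_per_s * np.clip(t, 0.0, fill_time)), cap)

    return lambda t: count(t) if np.ndim(t) else float(count(t))


def _step_count(n0: int, birth_times: np.ndarray) -> Callable:
    def count(t):
        t = np.asarray(t, dtype=float)
        return n0 + np.searchsorted(birth_times, t, side="right").astype(float)

    return lambda t: count(t) if np.ndim(t) else float(count(t))


def synthesize_trace(
    events: EventStream,
    noise: NoiseModel,
    sampling_rate: float = 1000.0,
    duration: float = 60.0,
    seed: int | np.random.SeedSequence = 0,
    start_time: float = 0.0,
    frequency: float = 1.5e6,
) -> PhaseTrace:
    """Render an event stream into a raw phase trace.

    The trace is baseline drift (slow sinusoid) + white Gaussian noise + one
    unimodal Gaussian bump per event.  Bump amplitude is log-normal around
    ``peak_amplitude_median``; full width at half maximum is Gaussian around
    ``peak_width_mean``.  Events outside ``[start_time, start_time+duration)``
    are ignored.  Events closer together than the mean peak width superpose
    additively (coincident passage) and trigger a warning.
    """
    if sampling_rate < 100.0:
        raise ValueError("sampling_rate must be >= 100 Hz to resolve ~20 ms peaks")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = start_time + np.arange(n) / sampling_rate
    x = np.zeros(n)

    if noise.drift_amplitude > 0 and noise.drift_period > 0:
        x += noise.drift_amplitude * np.sin(2.0 * np.pi * (t - start_time) / noise.drift_period)
    if noise.gaussian_sd > 0:
        x += rng.normal(0.0, noise.gaussian_sd, n)

    in_range = (events.times >= start_time) & (events.times < start_time + duration)
    ev = events.times[in_range]
    if ev.size > 1 and np.min(np.diff(ev)) < noise.peak_width_mean:
        warnings.warn(
            "events closer together than the peak width; peaks superposed additively",
            stacklevel=2,
        )
    min_fwhm = 2.0 / sampling_rate
    for te in ev:
        amp = noise.peak_amplitude_median * math.exp(rng.normal(0.0, noise.peak_amplitude_log_sd))
        fwhm = max(rng.normal(noise.peak_width_mean, noise.peak_width_sd), min_fwhm)
        sigma = fwhm / _FWHM_TO_SIGMA
        half = 5.0 * sigma
        i0 = max(0, int(math.floor((te - half - start_time) * sampling_rate)))
        i1 = min(n, int(math.ceil((te + half - start_time) * sampling_rate)) + 1)
        tt = t[i0:i1]
        x[i0:i1] += amp * np.exp(-0.5 * ((tt - te) / sigma) ** 2)

    return PhaseTrace(
        unit_id=events.unit_id,
        sampling_rate=sampling_rate,
        samples=x,
        start_time=start_time,
        frequency=frequency,
    )


@dataclass
class UnitTruth:
    """Ground truth for one simulated analysis unit."""

    params: ColonyParams
    events: EventStream
    fill_time: float
    cell_count_start: float
    cell_count_end: float


@dataclass
class SyntheticExperiment:
    """A full simulated experiment: continuous traces plus per-unit ground truth."""

    traces: list[PhaseTrace]
    truth: dict[str, UnitTruth]
    schedule: MultiplexSchedule | None = None
    media: MediaSchedule | None = None

    def __post_init__(self) -> None:
        missing = [tr.unit_id for tr in self.traces if tr.unit_id not in self.truth]
        if missing:
            raise ValueError(f"traces without a truth record: {missing}")


def apply_multiplex_schedule(experiment: SyntheticExperiment) -> list[PhaseTrace]:
    """Crop each unit's continuous trace to its scheduled recording windows.

    Returns one :class:`PhaseTrace` per (unit, window); gaps between windows
    contain no samples.  With no schedule the traces pass through unchanged
    (continuous recording).
    """
    if experiment.schedule is None or not experiment.schedule.entries:
        return [] if experiment.schedule is not None else list(experiment.traces)
    duration = max(tr.end_time for tr in experiment.traces)
    start = min(tr.start_time for tr in experiment.traces)
    windows = experiment.schedule.windows(duration - start, start=start)
    validate_nonoverlapping(windows)
    by_unit: dict[str, PhaseTrace] = {tr.unit_id: tr for tr in experiment.traces}
    segments: list[PhaseTrace] = []
    seg_index: dict[str, int] = {}
    for w in windows:
        tr = by_unit.get(w.unit_id)
        if tr is None:
            continue
        k = seg_index.get(w.unit_id, 0)
        seg = tr.crop(w.start, w.end, segment_index=k)
        if len(seg):
            segments.append(seg)
            seg_index[w.unit_id] = k + 1
    return segments
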
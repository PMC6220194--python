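"""Poisson counting statistics for the multiplexed readout.

Cell passages over an electrode pair are a Poisson process, so for a unit
sampled with ``k`` windows of length ``w`` seconds at true rate ``lam``
(events/s), the rate estimate — the mean of the per-window rates, which for
equal windows equals total count over total time — has standard error

    SEM = sqrt(lam / (k * w))

The precision therefore depends only on the *total* recording time
``T = k * w``, not on how it is partitioned into windows: many short or few
long recordings of the same total duration are statistically equivalent.
The flip side is the allocation rule for a shared analyzer: to reach equal
*relative* precision rho = SEM/lam across units, each unit needs total time
``T_i = 1 / (lam_i * rho^2)`` — slower-growing units need longer windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .schedule import MultiplexSchedule

__all__ = [
    "PrecisionQuery",
    "poisson_sem",
    "simulate_sem",
    "required_total_time",
    "cycles_for_precision",
    "allocate_windows",
    "predicted_sems",
]


@dataclass(frozen=True)
class PrecisionQuery:
    """A (rate, window length, cycle count) triple for precision queries."""

    event_rate: float  # events/s
    window_length: float  # s
    n_cycles: int

    def __post_init__(self) -> None:
        if self.event_rate <= 0 or self.window_length <= 0 or self.n_cycles <= 0:
            raise ValueError("event_rate, window_length and n_cycles must all be > 0")

    def sem(self) -> float:
        return poisson_sem(self.event_rate, self.window_length, self.n_cycles)


def poisson_sem(event_rate: float, window_length: float, n_cycles: int) -> float:
    """Standard error of the Poisson rate estimate: ``sqrt(lam / (k*w))``."""
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if window_length <= 0 or n_cycles <= 0:
        raise ValueError("window_length and n_cycles must be > 0")
    return math.sqrt(event_rate / (n_cycles * window_length))


def simulate_sem(
    event_rate: float,
    window_length: float,
    n_cycles: int,
    n_replicates: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Empirical SEM of the windowed rate estimate by Monte Carlo.

    Draws ``n_cycles`` Poisson(lam*w) counts per replicate, forms the
    per-replicate rate estimate (mean per-window rate), and returns the
    across-replicate standard deviation.  Converges to :func:`poisson_sem`
    as ``n_replicates`` grows.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if window_length <= 0 or n_cycles <= 0:
        raise ValueError("window_length and n_cycles must be > 0")
    if event_rate == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    counts = rng.poisson(event_rate * window_length, size=(n_replicates, n_cycles))
    estimates = counts.mean(axis=1) / window_length
    return float(np.std(estimates, ddof=1))


def required_total_time(event_rate: float, target_sem: float) -> float:
    """Total recording time needed for a target SEM: ``lam / sem^2`` seconds."""
    if target_sem <= 0:
        raise ValueError("target_sem must be > 0")
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    return event_rate / target_sem**2


def cycles_for_precision(event_rate: float, window_length: float, target_sem: float) -> int:
    """Number of cycles of a given window length needed for a target SEM.

    Fractional cycle counts are floored; when flooring loses precision, a
    warning reports the (slightly worse) achieved SEM.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    k_exact = required_total_time(event_rate, target_sem) / window_length
    k = max(1, math.floor(k_exact + 1e-9))
    if k < k_exact - 1e-9:
        achieved = poisson_sem(event_rate, window_length, k)
        warnings.warn(
            f"cycle count floored from {k_exact:.2f} to {k}; "
            f"achieved SEM {achieved:.4g} instead of {target_sem:.4g}",
            stacklevel=2,
        )
    return k


def allocate_windows(
    unit_rates: Mapping[str, float],
    target_relative_sem: float,
    switching_overhead: float = 0.0,
    n_cycles: int = 1,
) -> MultiplexSchedule:
    """Assign per-unit recording windows for equal relative precision.

    For unit ``i`` with rate ``lam_i`` and target relative SEM ``rho``
    (SEM/lam), the required total time is ``T_i = 1/(lam_i * rho^2)``;
    spread over ``n_cycles`` round-robin cycles, its per-cycle window is
    ``T_i / n_cycles``.  Slower units receive strictly longer windows.
    """
    if not unit_rates:
        raise ValueError("unit_rates must not be empty")
    if not 0.0 < target_relative_sem < 1.0:
        raise ValueError("target_relative_sem must be in (0, 1)")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    entries = []
    for unit_id, lam in unit_rates.items():
        if lam <= 0:
            raise ValueError(f"unit {unit_id!r}: event rate must be > 0")
        total = 1.0 / (lam * target_relative_sem**2)
        entries.append((unit_id, total / n_cycles))
    return MultiplexSchedule(entries, switching_overhead=switching_overhead)


def predicted_sems(
    schedule: MultiplexSchedule, unit_rates: Mapping[str, float], n_cycles: int = 1
) -> dict[str, float]:
    """Predicted absolute SEM per unit for a schedule run over ``n_cycles`` cycles."""
    return {
        uid: poisson_sem(unit_rates[uid], w, n_cycles)
        for uid, w in schedule.entries
        if uid in unit_rates
    }
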
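"""Canonical synthetic study designs.

Ready-made :class:`~padflux.config.ExperimentConfig` builders for the two
benchmark experiments the package validates itself against:

* :func:`two_unit_same_strain` — one strain cultured in two analysis units
  with different numbers of filled pads, multiplexed round-robin.  Because
  the normalized peak rate divides out colony size, both units should
  recover the same per-cell rate.
* :func:`calcium_switch_vph1` — a vph1-delta-like strain whose growth slows
  under 100 mM calcium: rich medium, then calcium medium, then rich medium
  again, with a ~40 s perfusion switch.  Validates condition segmentation
  and per-condition rate recovery.

Simulated recordings use 250 Hz sampling (>= 12 samples per 20 ms peak
half-width envelope, comfortably above the 2x30 Hz band Nyquist) and a
2e-3 degree detection threshold — the low end of the 1.5 MHz operating
range — because the 30 Hz low-pass passes a 20 ms bump at ~0.8 of its raw
amplitude.
"""

from __future__ import annotations

from .config import ExperimentConfig

#: Per-cell peak rate (events/h) both same-strain units are simulated at.
SAME_STRAIN_RATE_PER_H = 0.288

#: Per-cell peak rates (events/h) for the vph1-delta calcium-switch design.
VPH1_RATE_YPD_PER_H = 0.32
VPH1_RATE_CALCIUM_PER_H = 0.196

_SIM_SAMPLING_HZ = 250.0
_SIM_THRESHOLD_DEG = 2e-3


def two_unit_same_strain(
    seed: int,
    duration_s: float = 6 * 3600.0,
    rate_per_h: float = SAME_STRAIN_RATE_PER_H,
    sampling_rate_hz: float = _SIM_SAMPLING_HZ,
) -> ExperimentConfig:
    """Same strain in two units with 2 and 3 filled pads, multiplexed 240 s windows."""
    colony = {
        "growth_rate_per_cell_per_h": rate_per_h,
        "cells_per_pad": 400,
        "budding_index": 0.6,
    }
    return ExperimentConfig.model_validate(
        {
            "units": [
                {"unit_id": "u_2pads", "chamber_id": "chamber1", "pads_filled": 2, "colony": colony},
                {"unit_id": "u_3pads", "chamber_id": "chamber1", "pads_filled": 3, "colony": colony},
            ],
            "duration_s": duration_s,
            "seed": seed,
            "sampling_rate_hz": sampling_rate_hz,
            "threshold_deg": _SIM_THRESHOLD_DEG,
            "schedule": {"window_length_s": 240.0},
            "t_eis_s": 13 * 3600.0,
        }
    )


def calcium_switch_vph1(
    seed: int,
    ypd_hours: float = 6.0,
    calcium_hours: float = 10.0,
    recovery_hours: float = 6.0,
    sampling_rate_hz: float = _SIM_SAMPLING_HZ,
) -> ExperimentConfig:
    """One vph1-delta-like unit: YPD -> YPD+calcium -> YPD, continuous recording.

    The per-cell peak rate steps between the two condition rates with a 40 s
    linear ramp at each medium switch; recording is continuous and counted
    in 240 s windows, with windows overlapping a switch +/- 40 s discarded.
    """
    t1 = ypd_hours * 3600.0
    t2 = t1 + calcium_hours * 3600.0
    duration = t2 + recovery_hours * 3600.0
    return ExperimentConfig.model_validate(
        {
            "units": [
                {
                    "unit_id": "vph1d_r1",
                    "chamber_id": "chamber2",
                    "pads_filled": 4,
                    "colony": {
                        "growth_rate_per_cell_per_h": VPH1_RATE_YPD_PER_H,
                        "cells_per_pad": 400,
                        "budding_index": 0.6,
                        "condition_rates_per_h": {
                            "YPD": VPH1_RATE_YPD_PER_H,
                            "YPD+Ca": VPH1_RATE_CALCIUM_PER_H,
                        },
                    },
                }
            ],
            "duration_s": duration,
            "seed": seed,
            "sampling_rate_hz": sampling_rate_hz,
            "threshold_deg": _SIM_THRESHOLD_DEG,
            "schedule": None,
            "media": {
                "segments": [
                    {"start_s": 0.0, "condition": "YPD"},
                    {"start_s": t1, "condition": "YPD+Ca"},
                    {"start_s": t2, "condition": "YPD"},
                ],
                "switch_duration_s": 40.0,
            },
            "t_eis_s": 13 * 3600.0,
        }
    )
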
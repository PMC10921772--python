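"""Unit conversions used throughout the pipeline.

Conventions: time in seconds, flow in ml/min (positive = caudocranial),
areas in mm^2, stroke volumes in mm^3, velocities in cm/s, angles in
degrees. Every conversion between these lives here so the factors appear
exactly once.
"""

from __future__ import annotations

import numpy as np

#: ml/min -> mm^3/s  (1 ml = 1000 mm^3, 1 min = 60 s)
ML_MIN_TO_MM3_S = 1000.0 / 60.0

#: degrees of breathing cycle per percent of breathing cycle (360/100)
DEG_PER_PERCENT = 3.6


def flow_to_mean_velocity(flow_ml_min, area_mm2: float):
    """Mean velocity (cm/s) of a flow (ml/min) through a lumen of ``area_mm2``.

    v [cm/s] = Q [ml/min] * (1000/60) [mm^3/s per ml/min] / (area [mm^2] * 10 [mm/cm])
    """
    if area_mm2 <= 0:
        raise ValueError(f"area must be positive, got {area_mm2}")
    return np.asarray(flow_ml_min, dtype=float) * ML_MIN_TO_MM3_S / (area_mm2 * 10.0)


def velocity_to_flow(velocity_cm_s, area_mm2: float):
    """Flow (ml/min) carried by a plug of velocity ``velocity_cm_s`` over ``area_mm2``."""
    # cm/s * 10 = mm/s; * mm^2 = mm^3/s; / (1000/60) = ml/min
    return np.asarray(velocity_cm_s, dtype=float) * 10.0 * area_mm2 / ML_MIN_TO_MM3_S


def pixel_velocities_to_flow(velocities_cm_s, pixel_area_mm2: float):
    """Sum pixel velocities (cm/s) into a flow rate (ml/min).

    Each pixel contributes v * pixel_area * 10 mm^3/s; the total is converted
    to ml/min. ``velocities_cm_s`` may carry any leading shape; the sum runs
    over the last axis (or axes) supplied explicitly by the caller.
    """
    v = np.asarray(velocities_cm_s, dtype=float)
    return v * pixel_area_mm2 * 10.0 / ML_MIN_TO_MM3_S


def phase_percent_to_seconds(percent: float, breathing_period_s: float) -> float:
    """Convert a phase shift in % of the breathing cycle to seconds."""
    return percent / 100.0 * breathing_period_s


def phase_percent_to_degrees(percent: float) -> float:
    """Convert a phase shift in % of the breathing cycle to degrees (x3.6)."""
    return DEG_PER_PERCENT * percent


def phase_seconds_to_percent(seconds: float, breathing_period_s: float) -> float:
    """Convert a phase shift in seconds to % of the breathing cycle."""
    if breathing_period_s <= 0:
        raise ValueError("breathing period must be positive")
    return 100.0 * seconds / breathing_period_s
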
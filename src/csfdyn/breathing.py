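"""Quantification of free-breathing effects on CSF flow parameters.

The chest-belt signal delineates inspiration (ascending belt, thoracic
expansion) and expiration. Each cardiac cycle of the continuous flow record
is assigned to a breathing phase by its midpoint; the inspiratory and
expiratory cycles are averaged into Qt-Inspiration and Qt-Expiration, and
the difference of each cycle parameter p between them is the breathing
effect Delta-p. Because physiological responses lag the belt, the phase
assignment is swept over shifts Phi in [-3 s, +3 s] (0.1 s steps); the
resulting Delta-p(Phi) curve oscillates at the breathing frequency. Its
half peak-to-peak is the intensity of the breathing effect, and the grid
shift of the extreme closest to zero phase gives the phase lag, reported
in seconds, percent of the breathing cycle, and degrees.

Normalization: Delta-p% divides the intensity by the record-mean of p,
except for Qnet — which hovers near zero in CSF — where the mean Amplitude
is the denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .cycles import (
    CardiacCycle,
    QT_POINTS,
    ReconstructedQt,
    _lowpass,
    _stroke_volumes,
    average_cycles,
    compute_parameters,
    resample_cycle,
)
from .units import phase_percent_to_degrees, phase_seconds_to_percent

logger = logging.getLogger(__name__)

PARAMETERS = ("qnet", "amplitude", "sv", "tc")

IN = "IN"
EX = "EX"


@dataclass(frozen=True)
class BreathingSignal:
    """Chest-belt trace: uniformly sampled amplitude in arbitrary units."""

    time: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if time.ndim != 1 or time.shape != amp.shape or time.size < 2:
            raise ValueError("time and amplitude must be matching 1-D arrays")
        steps = np.diff(time)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-6 * steps.mean():
            raise ValueError("belt signal must be uniformly sampled")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "amplitude", amp)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class BreathingPhases:
    """Inspiration/expiration tiling of the complete breathing cycles.

    ``intervals`` is a list of (start, end, label) with label IN or EX,
    alternating and tiling [boundaries[0], boundaries[-1]); IN runs from a
    belt trough (end-expiration) to the following peak. Only complete
    trough-to-trough cycles are retained.
    """

    intervals: tuple
    boundaries: np.ndarray          # trough times delimiting complete cycles
    mean_breathing_period: float
    n_complete_cycles: int

    @property
    def window(self) -> tuple[float, float]:
        return float(self.boundaries[0]), float(self.boundaries[-1])

    def label_at(self, t: float) -> str | None:
        """IN/EX label of instant ``t`` (half-open intervals), else None."""
        starts = np.array([iv[0] for iv in self.intervals])
        i = int(np.searchsorted(starts, t, side="right")) - 1
        if i < 0:
            return None
        start, end, label = self.intervals[i]
        return label if start <= t < end else None


@dataclass(frozen=True)
class BreathingEffect:
    """Breathing effect of one parameter, from its Delta-p(Phi) curve."""

    parameter: str
    delta: float                 # intensity: half peak-to-peak, units of p
    delta_percent: float         # 100 * delta / normalization mean
    phi_s: float                 # shift of the extreme closest to zero
    phi_percent: float
    phi_deg: float
    delta_at_zero: float         # signed Delta-p at Phi = 0 (no shift)
    delta_at_zero_percent: float
    flat: bool = False           # True when the curve is degenerate (flat)


@dataclass(frozen=True)
class PhaseSweepResult:
    phi_grid: np.ndarray
    curves: dict                      # parameter -> Delta-p(Phi), native units
    effects: dict                     # parameter -> BreathingEffect
    n_insp: np.ndarray
    n_exp: np.ndarray
    mean_breathing_period: float
    normalization: dict               # parameter -> denominator used for %

    def as_dict(self) -> dict:
        out = {}
        for p, e in self.effects.items():
            out[p] = {
                "delta": e.delta,
                "delta_percent": e.delta_percent,
                "phi_s": e.phi_s,
                "phi_percent": e.phi_percent,
                "phi_deg": e.phi_deg,
                "delta_at_zero": e.delta_at_zero,
                "delta_at_zero_percent": e.delta_at_zero_percent,
                "flat": e.flat,
                "curve": self.curves[p].tolist(),
            }
        out["phi_grid_s"] = self.phi_grid.tolist()
        out["mean_breathing_period_s"] = self.mean_breathing_period
        return out


# ---------------------------------------------------------------------------
# breathing-phase delineation
# ---------------------------------------------------------------------------

def _belt_extrema(sig: BreathingSignal) -> tuple[np.ndarray, np.ndarray, float]:
    """Trough and peak sample times of a smoothed belt, with edge handling.

    A record often starts or ends exactly at an extremum (e.g. at
    end-expiration); ``find_peaks`` never reports boundary samples, so the
    first/last sample is admitted as an extremum when it dominates the
    adjacent quarter period.
    """
    x = sig.amplitude - sig.amplitude.mean()
    if np.allclose(x, 0):
        raise ValueError("flat belt signal: no breathing cycles")
    freqs = np.fft.rfftfreq(x.size, d=sig.dt)
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0
    f_dom = freqs[np.argmax(power)]
    if f_dom <= 0:
        raise ValueError("no oscillatory component in belt signal")
    period = 1.0 / f_dom
    # the smoothing and spacing must admit breaths well shorter than the
    # dominant period — in irregular records the spectral peak can sit at a
    # beat pattern of the breaths, and short breaths must still be detected
    # (not silently merged) for the irregularity check downstream to fire;
    # 1 Hz / 2 s bound the plausible adult breathing rate
    sm = _lowpass(sig.amplitude, sig.dt, cutoff_hz=max(3.0 * f_dom, 1.0))
    dist = max(1, int(round(min(0.3 * period, 2.0) / sig.dt)))
    quarter = max(1, int(round(0.25 * period / sig.dt)))

    def extrema(y: np.ndarray) -> np.ndarray:
        idx = list(find_peaks(y, distance=dist)[0])
        n = y.size
        if (not idx or idx[0] >= dist) and y[0] >= y[1:quarter + 1].max():
            idx.insert(0, 0)
        if (not idx or n - 1 - idx[-1] >= dist) and y[-1] >= y[-quarter - 1:-1].max():
            idx.append(n - 1)
        return np.asarray(idx, dtype=int)

    troughs = sig.time[extrema(-sm)]
    peaks = sig.time[extrema(sm)]
    return troughs, peaks, period


def delineate_phases(
    belt: BreathingSignal,
    max_period_cv: float = 0.5,
) -> BreathingPhases:
    """Label the inspiratory and expiratory intervals of a belt record.

    Inspiration = trough-to-peak (ascending belt, thoracic expansion);
    expiration = peak-to-trough. Only complete trough-to-trough cycles with
    exactly one interior peak are kept. Records with fewer than two complete
    cycles or with trough-interval variability above ``max_period_cv``
    (irregular breathing) are rejected.
    """
    troughs, peaks, _ = _belt_extrema(belt)
    intervals = []
    boundaries = []
    periods = []
    for t0, t1 in zip(troughs[:-1], troughs[1:]):
        inner = peaks[(peaks > t0) & (peaks < t1)]
        if inner.size != 1:
            logger.info("delineate_phases: skipping cycle %.2f-%.2f s "
                        "(%d interior peaks)", t0, t1, inner.size)
            continue
        pk = float(inner[0])
        intervals.append((float(t0), pk, IN))
        intervals.append((pk, float(t1), EX))
        if not boundaries or boundaries[-1] != t0:
            boundaries.append(float(t0))
        boundaries.append(float(t1))
        periods.append(t1 - t0)
    if len(periods) < 2:
        raise ValueError("fewer than 2 complete breathing cycles in the record")
    periods = np.asarray(periods)
    cv = periods.std() / periods.mean()
    if cv > max_period_cv:
        raise ValueError(
            f"irregular breathing: period variability {100 * cv:.0f}% exceeds "
            f"{100 * max_period_cv:.0f}%"
        )
    return BreathingPhases(
        intervals=tuple(intervals),
        boundaries=np.asarray(boundaries),
        mean_breathing_period=float(periods.mean()),
        n_complete_cycles=len(periods),
    )


# ---------------------------------------------------------------------------
# cycle assignment and per-phase reconstruction
# ---------------------------------------------------------------------------

def assign_cycles(
    cycles: Sequence[CardiacCycle],
    phases: BreathingPhases,
    shift: float = 0.0,
) -> tuple[list[CardiacCycle], list[CardiacCycle]]:
    """Split cycles into (inspiratory, expiratory) sets at a phase shift.

    A cycle joins the phase containing ``midpoint + shift`` (half-open
    intervals: a midpoint exactly on a boundary belongs to the interval
    starting there). Cycles whose shifted midpoint leaves the complete-cycle
    window are dropped for this shift.
    """
    insp, exp = [], []
    for c in cycles:
        label = phases.label_at(c.midpoint + shift)
        if label == IN:
            insp.append(c)
        elif label == EX:
            exp.append(c)
    return insp, exp


def reconstruct_phase_qt(
    insp: Sequence[CardiacCycle],
    exp: Sequence[CardiacCycle],
) -> tuple[ReconstructedQt, ReconstructedQt]:
    """Average the two phase sets into Qt-Inspiration and Qt-Expiration."""
    if not insp or not exp:
        raise ValueError("both breathing-phase sets need at least one cycle")
    return average_cycles(insp), average_cycles(exp)


def compute_delta(
    qt_in: ReconstructedQt,
    qt_ex: ReconstructedQt,
    segment_area: float | None = None,
) -> dict:
    """Inspiration-minus-expiration difference of each cycle parameter."""
    p_in = compute_parameters(qt_in, segment_area)
    p_ex = compute_parameters(qt_ex, segment_area)
    return {
        "qnet": p_in.qnet - p_ex.qnet,
        "amplitude": p_in.amplitude - p_ex.amplitude,
        "sv": p_in.sv - p_ex.sv,
        "tc": p_in.tc - p_ex.tc,
    }


# ---------------------------------------------------------------------------
# phase sweep
# ---------------------------------------------------------------------------

def curve_intensity(curve: np.ndarray) -> float:
    """Intensity of a Delta-p(Phi) curve: half its peak-to-peak range.

    For curve extremes of e.g. +144 and -137 mm^3 this is 140.5 mm^3 —
    robust also when the curve is not symmetric about zero.
    """
    curve = np.asarray(curve, dtype=float)
    return float((np.nanmax(curve) - np.nanmin(curve)) / 2.0)


def wrap_phase_shift(phi_s: float, breathing_period: float) -> float:
    """Map a shift into the principal breathing interval (-Tb/2, Tb/2].

    The Delta-p(Phi) curve repeats at the breathing period, so a shift near
    the grid edge is the replica of one |Tb| closer to zero; the reported
    phase (in percent of the breathing cycle) lives in (-50, 50].
    """
    wrapped = phi_s - breathing_period * np.floor(phi_s / breathing_period + 0.5)
    if wrapped <= -breathing_period / 2:
        wrapped += breathing_period
    return float(wrapped)


def select_extreme(phi_grid: np.ndarray, curve: np.ndarray,
                   breathing_period: float) -> float:
    """Shift (s) of the curve extreme with the smaller |Phi|.

    Of the curve's maximum and minimum — each first wrapped into the
    principal breathing interval — the one closer to zero shift is reported
    (ties broken toward the positive extreme, i.e. the maximum).
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    phi_max = wrap_phase_shift(float(phi_grid[np.nanargmax(curve)]),
                               breathing_period)
    phi_min = wrap_phase_shift(float(phi_grid[np.nanargmin(curve)]),
                               breathing_period)
    return phi_max if abs(phi_max) <= abs(phi_min) else phi_min


def _per_cycle_parameters(vec: np.ndarray, duration: float) -> dict:
    sv_pos, sv_neg = _stroke_volumes(vec, duration)
    return {
        "qnet": float(vec.mean()),
        "amplitude": float(np.ptp(vec)),
        "sv": 0.5 * (sv_pos + sv_neg),
        "tc": duration,
    }


def sweep_phase(
    cycles: Sequence[CardiacCycle],
    phases: BreathingPhases,
    segment_area: float | None = None,
    phi_min: float = -3.0,
    phi_max: float = 3.0,
    phi_step: float = 0.1,
    max_missing_fraction: float = 0.2,
) -> PhaseSweepResult:
    """Sweep the phase shift and quantify the breathing effect per parameter.

    At each shift on the inclusive grid the cycles are re-assigned, the two
    phase averages rebuilt, and Delta-p recorded. Grid points where either
    phase set is empty are missing; isolated gaps are filled by linear
    interpolation, but more than ``max_missing_fraction`` missing aborts.

    Returns the Delta-p(Phi) curves plus, per parameter: the intensity
    (half peak-to-peak), its percent normalization, the phase of the
    extreme closest to zero (s, %, degrees), and the signed Delta-p at
    zero shift.
    """
    if phases.n_complete_cycles < 2:
        raise ValueError("need at least 2 complete breathing cycles")
    n_grid = int(round((phi_max - phi_min) / phi_step)) + 1
    phi_grid = phi_min + phi_step * np.arange(n_grid)

    # resample every cycle once; the sweep only re-groups the 32-vectors
    vecs = np.stack([resample_cycle(c) for c in cycles])
    durations = np.array([c.duration for c in cycles])
    midpoints = np.array([c.midpoint for c in cycles])

    # normalization means from all cycles retained at zero shift
    labels0 = np.array([phases.label_at(m) or "" for m in midpoints])
    retained0 = labels0 != ""
    if not retained0.any():
        raise ValueError("no cardiac cycles fall inside the breathing window")
    per_cycle = [_per_cycle_parameters(v, d)
                 for v, d in zip(vecs[retained0], durations[retained0])]
    means = {p: float(np.mean([c[p] for c in per_cycle])) for p in PARAMETERS}
    norm = {p: (means["amplitude"] if p == "qnet" else means[p])
            for p in PARAMETERS}

    curves = {p: np.full(n_grid, np.nan) for p in PARAMETERS}
    n_insp = np.zeros(n_grid, dtype=int)
    n_exp = np.zeros(n_grid, dtype=int)
    for k, phi in enumerate(phi_grid):
        lab = [phases.label_at(m + phi) for m in midpoints]
        in_sel = np.array([l == IN for l in lab])
        ex_sel = np.array([l == EX for l in lab])
        n_insp[k], n_exp[k] = in_sel.sum(), ex_sel.sum()
        if n_insp[k] == 0 or n_exp[k] == 0:
            continue  # Delta-p undefined here: recorded as missing
        delta = _delta_from_groups(vecs, durations, in_sel, ex_sel)
        for p in PARAMETERS:
            curves[p][k] = delta[p]

    missing = np.isnan(curves[PARAMETERS[0]])
    if missing.mean() > max_missing_fraction:
        raise ValueError(
            f"{100 * missing.mean():.0f}% of phase-shift grid points have an "
            "empty breathing-phase set; record too short or too asymmetric"
        )
    if missing.any():
        ok = ~missing
        for p in PARAMETERS:
            curves[p][missing] = np.interp(phi_grid[missing], phi_grid[ok],
                                           curves[p][ok])

    tb = phases.mean_breathing_period
    zero_idx = int(np.argmin(np.abs(phi_grid)))
    effects = {}
    for p in PARAMETERS:
        curve = curves[p]
        intensity = curve_intensity(curve)
        scale = max(np.abs(curve).max(), 1.0)
        flat = bool(intensity <= 1e-9 * scale)
        phi_s = 0.0 if flat else select_extreme(phi_grid, curve, tb)
        phi_pct = phase_seconds_to_percent(phi_s, tb)
        d0 = float(curve[zero_idx])
        effects[p] = BreathingEffect(
            parameter=p,
            delta=intensity,
            delta_percent=100.0 * intensity / norm[p],
            phi_s=phi_s,
            phi_percent=phi_pct,
            phi_deg=phase_percent_to_degrees(phi_pct),
            delta_at_zero=d0,
            delta_at_zero_percent=100.0 * d0 / norm[p],
            flat=flat,
        )
    return PhaseSweepResult(
        phi_grid=phi_grid,
        curves=curves,
        effects=effects,
        n_insp=n_insp,
        n_exp=n_exp,
        mean_breathing_period=tb,
        normalization=norm,
    )


def _delta_from_groups(vecs, durations, in_sel, ex_sel) -> dict:
    """Delta-p between the mean inspiratory and expiratory cycles."""
    out = {}
    p_in = _per_cycle_parameters(vecs[in_sel].mean(axis=0),
                                 float(durations[in_sel].mean()))
    p_ex = _per_cycle_parameters(vecs[ex_sel].mean(axis=0),
                                 float(durations[ex_sel].mean()))
    for p in PARAMETERS:
        out[p] = p_in[p] - p_ex[p]
    return out
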
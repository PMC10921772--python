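"""Synthetic CSF flow records with known cardiac/breathing structure.

The generator emulates what a real-time phase-contrast acquisition delivers:
a ~45 s continuous flow signal (one sample every 78-96 ms) carrying a
cardiac oscillation (~0.87 s period) whose amplitude, period and net offset
are modulated at the breathing period (~3.4 s), plus a synchronized
chest-belt trace, and optionally a rendered velocity-map image series with
noise, a constant eddy-current-like offset and velocity aliasing.

Modulation model
----------------
Each cardiac cycle i has a period drawn from the breathing phase ``phi``
of its own midpoint (the beat responds as a whole, matching how the
analysis assigns each beat by its midpoint), while the flow amplitude and
net offset follow smooth breathing-locked envelopes — real CSF flow is
continuous, and stepping the envelope at each beat boundary would put
artificial discontinuities exactly where the analysis hunts for minima:

    Tc_i   = T0 * (1 + m_Tc * sin(2*pi*phi_i + lag_Tc))
    A(t)   = A0 * (1 + m_A  * sin(2*pi*t/Tb + lag_A))
    N(t)   = N0 + c_N * A0  * sin(2*pi*t/Tb + lag_N)

and Q(t) = N(t) + A(t) * w(psi(t)) with psi the within-cycle phase. The
per-cycle ground truth records the envelope values at each midpoint.

The configured depths are expressed directly as the inspiration-minus-
expiration contrast the analysis should measure (Delta-p%). Since the mean
of ``sin`` over the inspiratory half-cycle is 2/pi, a sinusoidal modulation
of relative depth m produces a half-cycle contrast of m*4/pi, so the
generator uses m = depth_percent * pi / 400. The net-flow modulation is
additive and scaled by the base amplitude A0, because CSF net flow hovers
near zero and its percent contrast is conventionally normalized by the
flow amplitude; its envelope coefficient c_N is additionally divided by
sinc(T0/Tb), because a cycle's measured net flow is the envelope averaged
over the beat, which attenuates a sinusoid of period Tb by exactly that
factor. With these conventions and the analysis' shift sign, the recovered
phase (in degrees of the breathing cycle) equals the configured
``phase_lag_deg``.

The belt is a raised cosine starting at end-expiration: its ascending half
(breathing phase in [0, 0.5)) is inspiration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .breathing import BreathingSignal
from .cycles import FlowSeries
from .image import VelocityMapSeries
from .units import velocity_to_flow

#: relative modulation depth per percent of measured insp/exp contrast
DEPTH_PERCENT_TO_M = math.pi / 400.0

MODULATED = ("amplitude", "tc", "qnet")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic free-breathing CSF acquisition.

    Defaults reflect a spinal (C2-C3 level) acquisition: cardiac period
    0.832 s, flow amplitude 338 ml/min peak-to-peak, net flow 9.4 ml/min,
    breathing period 3.4 s, 45 s of data at 96 ms per frame.
    """

    duration: float = 45.0                  # s
    frame_interval: float = 0.096           # s per velocity map
    base_cardiac_period: float = 0.832      # T0, s
    base_amplitude: float = 338.0           # A0, ml/min, peak-to-peak
    base_net_flow: float = 9.4              # N0, ml/min
    breathing_period: float = 3.4           # Tb, s
    #: measured insp/exp contrast to inject, % per parameter
    modulation_depth_percent: dict = field(
        default_factory=lambda: {"amplitude": 0.0, "tc": 0.0, "qnet": 0.0})
    #: phase lag per parameter, degrees of the breathing cycle
    phase_lag_deg: dict = field(
        default_factory=lambda: {"amplitude": 0.0, "tc": 0.0, "qnet": 0.0})
    waveform: str = "csf_like"              # "sinusoid" | "csf_like"
    noise_sd: float = 0.0                   # ml/min, additive Gaussian
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 2 * self.breathing_period:
            raise ValueError(
                "duration must exceed two breathing periods "
                f"({self.duration} s <= 2 x {self.breathing_period} s): too "
                "few complete breathing cycles")
        if not (self.breathing_period > self.base_cardiac_period > 0):
            raise ValueError("need breathing_period > cardiac period > 0")
        if self.frame_interval >= self.base_cardiac_period / 4:
            raise ValueError("frame_interval must be below a quarter cardiac period")
        if self.waveform not in ("sinusoid", "csf_like"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        for p in MODULATED:
            if self.modulation_depth_percent.get(p, 0.0) < 0:
                raise ValueError("modulation depths must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated record, one entry per complete cycle."""

    injected_depth_percent: dict
    injected_phase_deg: dict
    cycle_starts: np.ndarray          # s
    cycle_durations: np.ndarray       # Tc_i, s
    cycle_amplitudes: np.ndarray      # A_i, ml/min
    cycle_net_flows: np.ndarray       # N_i, ml/min
    cycle_midpoints: np.ndarray       # s
    cycle_breathing_phases: np.ndarray  # phase of midpoint, in [0, 1)
    cycle_labels: np.ndarray          # "IN" (phase < 0.5) or "EX"
    breathing_boundaries: np.ndarray  # k * Tb within the record, s

    def as_dict(self) -> dict:
        return {
            "injected_depth_percent": self.injected_depth_percent,
            "injected_phase_deg": self.injected_phase_deg,
            "cycle_starts_s": self.cycle_starts.tolist(),
            "cycle_durations_s": self.cycle_durations.tolist(),
            "cycle_amplitudes_ml_min": self.cycle_amplitudes.tolist(),
            "cycle_net_flows_ml_min": self.cycle_net_flows.tolist(),
            "cycle_midpoints_s": self.cycle_midpoints.tolist(),
            "cycle_breathing_phases": self.cycle_breathing_phases.tolist(),
            "cycle_labels": self.cycle_labels.tolist(),
            "breathing_boundaries_s": self.breathing_boundaries.tolist(),
        }


@dataclass(frozen=True)
class ImageRenderConfig:
    """How to paint a flow signal onto velocity maps."""

    grid_size: tuple[int, int] = (32, 32)     # H x W pixels
    pixel_spacing: float = 2.0                # mm
    #: default lumen: 6x6 pixel block (144 mm^2, spinal-canal scale, so the
    #: default flow amplitudes map to plug velocities well inside the VENC)
    roi_pixels: tuple = tuple(
        (r, c) for r in range(13, 19) for c in range(13, 19))
    venc: float = 10.0                        # cm/s
    background_offset: float = 0.0            # cm/s, eddy-current-like bias
    stationary_tissue_noise_sd: float = 0.0   # cm/s
    alias: bool = False

    def __post_init__(self):
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if len(self.roi_pixels) == 0 or self.pixel_spacing <= 0:
            raise ValueError("ROI must be nonempty with positive pixel spacing")
        h, w = self.grid_size
        for r, c in self.roi_pixels:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"ROI pixel {(r, c)} outside the {h}x{w} grid")

    @property
    def roi_area(self) -> float:
        """Lumen area, mm^2."""
        return len(self.roi_pixels) * self.pixel_spacing ** 2


# ---------------------------------------------------------------------------
# cardiac waveform templates
# ---------------------------------------------------------------------------

def _csf_like_constants() -> tuple[float, float, float]:
    """Phase origin (at the waveform minimum), mean and peak-to-peak of the
    raw two-harmonic template, computed once on a dense grid."""
    psi = np.linspace(0.0, 1.0, 4096, endpoint=False)
    raw = np.sin(2 * np.pi * psi) + 0.35 * np.sin(4 * np.pi * psi + np.pi / 3)
    return float(psi[np.argmin(raw)]), float(raw.mean()), float(np.ptp(raw))


_CSF_PSI0, _CSF_MEAN, _CSF_PTP = _csf_like_constants()


def cardiac_template(phase, waveform: str = "csf_like") -> np.ndarray:
    """Normalized cardiac flow waveform w(phase): zero mean, unit
    peak-to-peak, minimum at phase 0 (cycles are cut minimum-to-minimum).

    ``sinusoid`` is -cos(2*pi*phase)/2, for closed-form oracles;
    ``csf_like`` is a two-harmonic template with the asymmetric systolic
    trough of real aqueduct/spinal CSF curves.
    """
    phase = np.asarray(phase, dtype=float)
    if waveform == "sinusoid":
        return -0.5 * np.cos(2 * np.pi * phase)
    if waveform == "csf_like":
        psi = phase + _CSF_PSI0
        raw = (np.sin(2 * np.pi * psi)
               + 0.35 * np.sin(4 * np.pi * psi + np.pi / 3))
        return (raw - _CSF_MEAN) / _CSF_PTP
    raise ValueError(f"unknown waveform {waveform!r}")


# ---------------------------------------------------------------------------
# record generation
# ---------------------------------------------------------------------------

def _modulation(config: SimulationConfig, param: str, phase) -> np.ndarray:
    """Sinusoidal modulation factor m*sin(2*pi*phase + lag) for ``param``."""
    m = config.modulation_depth_percent.get(param, 0.0) * DEPTH_PERCENT_TO_M
    lag = math.radians(config.phase_lag_deg.get(param, 0.0))
    return m * np.sin(2 * np.pi * np.asarray(phase, dtype=float) + lag)


def _build_cycles(config: SimulationConfig) -> list[tuple[float, float, float, float, float]]:
    """Sequential (start, Tc, A, N, phase_mid) tuples covering the record.

    Tc_i depends on the breathing phase of the cycle's own midpoint, which
    depends on Tc_i; a few fixed-point iterations resolve it (the
    modulation is a few percent, so convergence is immediate). A and N are
    the envelope values at the midpoint — the cycle's ground truth.
    """
    tb = config.breathing_period
    cycles = []
    t = 0.0
    while t < config.duration:
        tc = config.base_cardiac_period
        for _ in range(6):
            phi = ((t + tc / 2.0) / tb) % 1.0
            tc = config.base_cardiac_period * (1.0 + _modulation(config, "tc", phi))
        phi = ((t + tc / 2.0) / tb) % 1.0
        amp = config.base_amplitude * (1.0 + _modulation(config, "amplitude", phi))
        net = config.base_net_flow + config.base_amplitude * _modulation(
            config, "qnet", phi)
        cycles.append((t, float(tc), float(amp), float(net), float(phi)))
        t += tc
    return cycles


def _beat_mean_attenuation(config: SimulationConfig) -> float:
    """Attenuation of a breathing-period sinusoid averaged over one beat.

    sinc(T0/Tb): a cycle's measured net flow is the mean of the offset
    envelope over the beat, not its midpoint value.
    """
    x = math.pi * config.base_cardiac_period / config.breathing_period
    return math.sin(x) / x


def generate_flow_record(
    config: SimulationConfig,
) -> tuple[FlowSeries, BreathingSignal, SyntheticTruth]:
    """Generate a flow record, synchronized belt signal and ground truth.

    With all modulation depths zero and no noise the signal is exactly
    periodic with the base cardiac period. The belt is a raised cosine
    whose ascending half is inspiration; its troughs sit at multiples of
    the breathing period, synchronized with the breathing phase used to
    modulate the cycles. All randomness comes from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cycles = _build_cycles(config)
    starts = np.array([c[0] for c in cycles])
    tb = config.breathing_period

    t = np.arange(0.0, config.duration, config.frame_interval)
    idx = np.searchsorted(starts, t, side="right") - 1
    # within-cycle phase from the per-beat periods
    psi = np.empty_like(t)
    for i, (start, tc, _, _, _) in enumerate(cycles):
        sel = idx == i
        if sel.any():
            psi[sel] = (t[sel] - start) / tc
    amp_env = config.base_amplitude * (
        1.0 + _modulation(config, "amplitude", t / tb))
    net_env = config.base_net_flow + (
        config.base_amplitude / _beat_mean_attenuation(config)
    ) * _modulation(config, "qnet", t / tb)
    q = net_env + amp_env * cardiac_template(psi, config.waveform)
    if config.noise_sd > 0:
        q = q + rng.normal(0.0, config.noise_sd, size=q.size)
    flow = FlowSeries(t, q)

    belt = BreathingSignal(
        t, 0.5 * (1.0 - np.cos(2 * np.pi * t / config.breathing_period)))

    complete = [c for c in cycles if c[0] + c[1] <= config.duration + 1e-9]
    phases = np.array([c[4] for c in complete])
    truth = SyntheticTruth(
        injected_depth_percent={p: config.modulation_depth_percent.get(p, 0.0)
                                for p in MODULATED},
        injected_phase_deg={p: config.phase_lag_deg.get(p, 0.0)
                            for p in MODULATED},
        cycle_starts=np.array([c[0] for c in complete]),
        cycle_durations=np.array([c[1] for c in complete]),
        cycle_amplitudes=np.array([c[2] for c in complete]),
        cycle_net_flows=np.array([c[3] for c in complete]),
        cycle_midpoints=np.array([c[0] + c[1] / 2.0 for c in complete]),
        cycle_breathing_phases=phases,
        cycle_labels=np.where(phases < 0.5, "IN", "EX"),
        breathing_boundaries=np.arange(
            0.0, config.duration + 1e-9, config.breathing_period),
    )
    return flow, belt, truth


# ---------------------------------------------------------------------------
# velocity-map rendering
# ---------------------------------------------------------------------------

def render_velocity_series(
    flow: FlowSeries,
    img: ImageRenderConfig,
    seed: int = 0,
) -> VelocityMapSeries:
    """Paint a flow signal onto velocity maps (uniform plug profile).

    At each frame every ROI pixel carries the plug velocity implied by the
    flow and the ROI area; all pixels (lumen and background alike — an
    eddy-current bias is spatially global) additionally carry
    ``background_offset`` plus Gaussian noise. With ``alias`` the stored
    velocities wrap into [-VENC, VENC) as a phase measurement would.

    Raises ``ValueError`` if aliasing is requested while the true velocity
    reaches 3*VENC, where a single unwrap no longer restores it.
    """
    rng = np.random.default_rng(seed)
    h, w = img.grid_size
    n = flow.time.size
    # plug velocity: Q spread uniformly over the lumen area
    v_roi = np.asarray(flow.flow, dtype=float) / velocity_to_flow(1.0, img.roi_area)
    if img.alias and np.abs(v_roi + img.background_offset).max() >= 3.0 * img.venc:
        raise ValueError("true velocity reaches 3*VENC: single-wrap aliasing "
                         "cannot be rendered unambiguously")
    frames = np.full((n, h, w), img.background_offset, dtype=float)
    rows = [p[0] for p in img.roi_pixels]
    cols = [p[1] for p in img.roi_pixels]
    frames[:, rows, cols] += v_roi[:, None]
    if img.stationary_tissue_noise_sd > 0:
        frames += rng.normal(0.0, img.stationary_tissue_noise_sd, size=frames.shape)
    if img.alias:
        frames = np.mod(frames + img.venc, 2.0 * img.venc) - img.venc
    return VelocityMapSeries(frames, img.pixel_spacing, flow.dt, img.venc)


def true_mask(img: ImageRenderConfig):
    """Boolean H x W array of the rendered ROI (for ground-truth tests)."""
    h, w = img.grid_size
    m = np.zeros((h, w), dtype=bool)
    for r, c in img.roi_pixels:
        m[r, c] = True
    return m
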
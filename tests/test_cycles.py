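"""Cycle segmentation, resampling, averaging and cycle parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import csfdyn as cd
from csfdyn.cycles import CardiacCycle, QT_POINTS


def make_flow(duration=45.0, dt=0.09, period=0.9, amplitude=160.0, offset=0.0):
    t = np.arange(0.0, duration, dt)
    return cd.FlowSeries(t, offset + amplitude * np.sin(2 * np.pi * t / period))


# ---------------------------------------------------------------------------
# minima detection and splitting
# ---------------------------------------------------------------------------

def test_minima_of_pure_sinusoid():
    flow = make_flow()
    minima = cd.detect_cycle_minima(flow)
    assert 49 <= len(minima) <= 50
    spacing = np.diff(minima)
    assert np.all(np.abs(spacing - 0.9) <= 0.09 + 1e-9)


def test_constant_signal_rejected():
    t = np.arange(0.0, 45.0, 0.09)
    with pytest.raises(ValueError, match="cardiac"):
        cd.detect_cycle_minima(cd.FlowSeries(t, np.full(t.size, 3.0)))


def test_short_record_rejected():
    flow = make_flow(duration=3.0)
    with pytest.raises(ValueError, match="short"):
        cd.detect_cycle_minima(flow)


def test_detected_periods_match_truth(modulated_record):
    """Per-cycle periods of an RSA-modulated record agree with the ground
    truth within one frame interval each."""
    cfg, flow, _, truth = modulated_record
    dense = cd.cycles.upsample_flow(flow)
    minima = cd.detect_cycle_minima(dense)
    cycles = cd.split_cycles(dense, minima)
    for c in cycles:
        k = np.argmin(np.abs(truth.cycle_starts - c.start))
        assert abs(c.duration - truth.cycle_durations[k]) < cfg.frame_interval


def test_split_fencepost():
    # 10 equal cycles -> 11 minima -> 10 segments; a 45 s sinusoid at 0.9 s
    # yields one segment fewer than minima
    flow = make_flow(duration=9.95, period=1.0, dt=0.05)
    minima = cd.detect_cycle_minima(flow)
    cycles = cd.split_cycles(flow, minima)
    assert len(cycles) == len(minima) - 1


def test_duration_gate_discards_gap():
    flow = make_flow()
    minima = list(cd.detect_cycle_minima(flow))
    dropped = minima.pop(10)  # simulate one missed minimum
    cycles = cd.split_cycles(flow, minima)
    durations = [c.duration for c in cycles]
    assert max(durations) < 1.4 * np.median(durations)
    # the double-length segment around the gap is gone
    assert not any(abs(c.start - minima[9]) < 1e-9 and c.duration > 1.5
                   for c in cycles)
    assert len(cycles) == len(minima) - 2


def test_split_requires_two_minima():
    flow = make_flow()
    with pytest.raises(ValueError):
        cd.split_cycles(flow, [1.0])


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_is_exact_at_knots():
    phases = np.arange(QT_POINTS) / QT_POINTS
    values = np.sin(2 * np.pi * phases) + 3.0
    cyc = CardiacCycle(0.0, 1.0, phases, values)
    assert np.allclose(cd.resample_cycle(cyc), values)


def test_resample_sinusoid_from_10_points():
    t = np.arange(11) / 10.0
    cyc = CardiacCycle(0.0, 1.0, t, -np.cos(2 * np.pi * t))
    out = cd.resample_cycle(cyc)
    expected = -np.cos(2 * np.pi * np.arange(QT_POINTS) / QT_POINTS)
    assert np.abs(out - expected).max() < 0.01 * 2.0  # < 1 % of amplitude


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-100, 100), min_size=5, max_size=20, unique=True))
def test_resample_never_overshoots_data_range(values):
    """Shape-preserving interpolation stays within the sample range."""
    v = np.asarray(values)
    t = np.linspace(0.0, 1.0, v.size)
    out = cd.resample_cycle(CardiacCycle(0.0, 1.0, t, v))
    assert out.max() <= v.max() + 1e-9
    assert out.min() >= v.min() - 1e-9


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------

def test_average_identities():
    t = np.linspace(0.0, 0.9, 12)
    a = CardiacCycle(0.0, 0.9, t, np.sin(2 * np.pi * t / 0.9))
    b = CardiacCycle(0.0, 0.9, t, 2.0 + np.sin(2 * np.pi * t / 0.9))
    same = cd.average_cycles([a, a])
    assert np.allclose(same.values, cd.resample_cycle(a))
    both = cd.average_cycles([a, b])
    assert np.allclose(both.values,
                       (cd.resample_cycle(a) + cd.resample_cycle(b)) / 2)
    assert both.n_cycles == 2 and both.tc == pytest.approx(0.9)
    with pytest.raises(ValueError):
        cd.average_cycles([])


def test_reconstruction_matches_generator_template(quiet_record):
    """Zero-modulation noiseless record: the reconstructed 32-point cycle
    equals the generator's template within 1 % of the flow amplitude."""
    cfg, flow, _, _ = quiet_record
    qt, _, _ = cd.reconstruct(flow)
    template = cfg.base_net_flow + cfg.base_amplitude * cd.cardiac_template(
        np.arange(QT_POINTS) / QT_POINTS, cfg.waveform)
    assert np.abs(qt.values - template).max() < 0.01 * cfg.base_amplitude
    assert qt.tc == pytest.approx(cfg.base_cardiac_period, rel=0.01)


# ---------------------------------------------------------------------------
# cycle parameters
# ---------------------------------------------------------------------------

def sinusoid_qt(amplitude=160.0, tc=0.87):
    values = amplitude * np.sin(2 * np.pi * np.arange(QT_POINTS) / QT_POINTS)
    return cd.ReconstructedQt(values, tc, 1)


def test_parameters_of_pure_sinusoid():
    a, tc = 160.0, 0.87
    p = cd.compute_parameters(sinusoid_qt(a, tc))
    assert p.qnet == pytest.approx(0.0, abs=1e-9)
    assert p.amplitude == pytest.approx(2 * a, rel=0.005)
    # closed-form half-sine integral: SV = A * Tc * 1000 / (60 pi)
    assert p.sv == pytest.approx(a * tc * 1000 / (60 * np.pi), rel=0.005)
    assert p.sv_pos == pytest.approx(p.sv_neg, rel=1e-9)


def test_parameters_of_constant_flow():
    c, tc = 12.0, 0.8
    qt = cd.ReconstructedQt(np.full(QT_POINTS, c), tc, 1)
    p = cd.compute_parameters(qt)
    assert p.amplitude == 0.0
    assert p.sv_pos == pytest.approx(c * tc * 1000 / 60)
    assert p.sv_neg == 0.0
    assert p.sv == pytest.approx(p.sv_pos / 2)


def test_peak_velocities_from_area():
    values = np.zeros(QT_POINTS)
    values[5], values[20] = 10.0, -6.0
    p = cd.compute_parameters(cd.ReconstructedQt(values, 0.87, 1),
                              segment_area=3.0)
    assert p.vmax == pytest.approx(10.0 * (1000 / 60) / 30.0)  # ~5.6 cm/s
    assert p.vmin == pytest.approx(6.0 * (1000 / 60) / 30.0)
    with pytest.raises(ValueError):
        cd.compute_parameters(sinusoid_qt(), segment_area=-1.0)


def test_sign_flip_swaps_directional_parameters():
    qt = sinusoid_qt()
    qt2 = cd.ReconstructedQt(-qt.values, qt.tc, 1)
    p1 = cd.compute_parameters(qt, segment_area=3.0)
    p2 = cd.compute_parameters(qt2, segment_area=3.0)
    assert p2.sv_pos == pytest.approx(p1.sv_neg)
    assert p2.sv_neg == pytest.approx(p1.sv_pos)
    assert p2.vmax == pytest.approx(p1.vmin)
    assert p2.vmin == pytest.approx(p1.vmax)
    assert p2.sv == pytest.approx(p1.sv)
    assert p2.amplitude == pytest.approx(p1.amplitude)


def test_flow_offset_shifts_qnet_only():
    qt = sinusoid_qt()
    shifted = cd.ReconstructedQt(qt.values + 7.0, qt.tc, 1)
    p1, p2 = cd.compute_parameters(qt), cd.compute_parameters(shifted)
    assert p2.qnet - p1.qnet == pytest.approx(7.0)
    assert p2.amplitude == pytest.approx(p1.amplitude)
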
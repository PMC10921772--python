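"""Breathing-phase delineation and the phase-shift sweep statistic."""

import numpy as np
import pytest

import csfdyn as cd
from csfdyn.breathing import EX, IN, wrap_phase_shift

from conftest import C2C3_DEPTHS, C2C3_LAGS


def cosine_belt(tb=3.4, duration=45.0, dt=0.096, t_shift=0.0, sign=1.0):
    t = np.arange(0.0, duration, dt)
    return cd.BreathingSignal(
        t, sign * 0.5 * (1 - np.cos(2 * np.pi * (t + t_shift) / tb)))


def manual_phases(tb=3.4, n=12):
    """Analytically exact IN/EX tiling for assignment unit tests."""
    intervals = []
    for k in range(n):
        intervals.append((k * tb, k * tb + tb / 2, IN))
        intervals.append((k * tb + tb / 2, (k + 1) * tb, EX))
    return cd.BreathingPhases(tuple(intervals),
                              np.arange(n + 1) * tb, tb, n)


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------

def test_raised_cosine_belt_delineation():
    phases = cd.delineate_phases(cosine_belt())
    assert phases.n_complete_cycles == 13
    assert phases.mean_breathing_period == pytest.approx(3.4, abs=0.05)
    for start, end, label in phases.intervals:
        assert end - start == pytest.approx(1.7, abs=0.1)


def test_monotone_belt_rejected():
    t = np.arange(0.0, 45.0, 0.096)
    with pytest.raises(ValueError):
        cd.delineate_phases(cd.BreathingSignal(t, t.copy()))


def test_irregular_breathing_rejected():
    # alternating 2.2 s / 10 s breaths: period variability well over 50 %
    periods = [2.2, 10.0] * 4
    knots = np.concatenate(([0.0], np.cumsum(periods)))
    t = np.arange(0.0, knots[-1], 0.096)
    k = np.searchsorted(knots, t, side="right") - 1
    phase = (t - knots[k]) / np.asarray(periods)[k]
    belt = cd.BreathingSignal(t, 0.5 * (1 - np.cos(2 * np.pi * phase)))
    with pytest.raises(ValueError):
        cd.delineate_phases(belt)


def test_inverted_belt_swaps_labels():
    ph = cd.delineate_phases(cosine_belt())
    inv = cd.delineate_phases(cosine_belt(sign=-1.0))
    for t in np.arange(5.0, 40.0, 0.37):
        a, b = ph.label_at(t), inv.label_at(t)
        if a is not None and b is not None:
            assert a != b


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def dummy_cycle(midpoint, duration=0.8):
    t = np.linspace(midpoint - duration / 2, midpoint + duration / 2, 9)
    return cd.CardiacCycle(t[0], t[-1], t, np.sin(t))


def test_boundary_midpoint_joins_interval_starting_there():
    phases = manual_phases()
    # midpoint exactly at an EX->IN boundary (t = Tb) is inspiratory
    insp, exp = cd.assign_cycles([dummy_cycle(3.4)], phases, shift=0.0)
    assert len(insp) == 1 and len(exp) == 0
    # and exactly at the IN->EX boundary is expiratory
    insp, exp = cd.assign_cycles([dummy_cycle(1.7)], phases, shift=0.0)
    assert len(exp) == 1 and len(insp) == 0


def test_shift_by_full_breathing_period_is_identity_for_interior():
    phases = manual_phases()
    cycles = [dummy_cycle(m) for m in np.arange(4.0, 36.0, 0.83)]
    a = cd.assign_cycles(cycles, phases, shift=0.0)
    b = cd.assign_cycles(cycles, phases, shift=3.4)
    assert [c.midpoint for c in a[0]] == [c.midpoint for c in b[0]]
    assert [c.midpoint for c in a[1]] == [c.midpoint for c in b[1]]


def test_out_of_window_cycles_dropped():
    phases = manual_phases(n=2)  # window [0, 6.8]
    insp, exp = cd.assign_cycles([dummy_cycle(7.5)], phases, shift=0.0)
    assert not insp and not exp


def test_assignments_match_generator_truth(quiet_record):
    _, flow, belt, truth = quiet_record
    _, _, cycles = cd.reconstruct(flow)
    phases = cd.delineate_phases(belt)
    insp, exp = cd.assign_cycles(cycles, phases, shift=0.0)
    insp_mids = {round(c.midpoint, 3) for c in insp}
    matched = mismatched = 0
    for mid, label in zip(truth.cycle_midpoints, truth.cycle_labels):
        near = [c for c in insp + exp if abs(c.midpoint - mid) < 0.25]
        if not near:
            continue
        got = IN if round(near[0].midpoint, 3) in insp_mids else EX
        if got == label:
            matched += 1
        else:
            mismatched += 1
    assert matched > 0.9 * (matched + mismatched)


# ---------------------------------------------------------------------------
# deltas and the sweep
# ---------------------------------------------------------------------------

def test_compute_delta_identities():
    values = 100 * np.sin(2 * np.pi * np.arange(32) / 32)
    qt = cd.ReconstructedQt(values, 0.85, 4)
    zero = cd.compute_delta(qt, qt)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in zero.values())
    up = cd.ReconstructedQt(values * 1.05, 0.85, 4)
    dn = cd.ReconstructedQt(values * 0.95, 0.85, 4)
    d = cd.compute_delta(up, dn)
    assert d["amplitude"] == pytest.approx(0.10 * 200.0, rel=1e-9)


def test_worked_example_intensity_and_extreme_choice():
    """Curve extremes +144 / -137 mm^3 give intensity 140.5 mm^3; of the
    extremes at -9 % and +41 % of a 3.4 s cycle, -9 % (0.3 s) is chosen and
    converts to -32.4 deg."""
    tb = 3.4
    grid = np.round(np.arange(-3.0, 3.01, 0.1), 10)
    curve = 140.5 * np.cos(2 * np.pi * (grid + 0.3) / tb) + 3.5
    assert cd.curve_intensity([144.0, -137.0]) == pytest.approx(140.5)
    phi = cd.select_extreme(grid, curve, tb)
    assert phi == pytest.approx(-0.3)
    pct = cd.phase_seconds_to_percent(phi, tb)
    assert round(pct) == -9
    assert cd.phase_percent_to_degrees(round(pct)) == pytest.approx(-32.4)


def test_wrap_phase_shift_principal_interval():
    assert wrap_phase_shift(3.0, 3.4) == pytest.approx(-0.4)
    assert wrap_phase_shift(-3.0, 3.4) == pytest.approx(0.4)
    assert wrap_phase_shift(1.7, 3.4) == pytest.approx(1.7)   # (−50, 50] -> +50
    assert wrap_phase_shift(-1.7, 3.4) == pytest.approx(1.7)


def test_zero_depth_sweep_is_flat(quiet_record):
    _, flow, belt, _ = quiet_record
    _, _, cycles = cd.reconstruct(flow)
    res = cd.sweep_phase(cycles, cd.delineate_phases(belt))
    for p in ("qnet", "amplitude", "sv", "tc"):
        # residual curve well below 1 % of the normalization scale
        assert np.abs(res.curves[p]).max() < 0.005 * res.normalization[p]


def test_joint_recovery_noiseless(modulated_record):
    """Simultaneous spinal-level modulations are recovered from a noiseless
    record: intensities within 20 % relative, phases within 15 deg."""
    _, flow, belt, _ = modulated_record
    _, _, cycles = cd.reconstruct(flow)
    res = cd.sweep_phase(cycles, cd.delineate_phases(belt))
    for p in ("tc", "amplitude", "qnet"):
        e = res.effects[p]
        assert e.delta_percent == pytest.approx(C2C3_DEPTHS[p], rel=0.20)
        assert abs(e.phi_deg - C2C3_LAGS[p]) < 15.0


def test_sweep_periodicity_at_breathing_period():
    """Delta-p(Phi) repeats at the breathing period (long record, so edge
    subsets are negligible): deviation < 5 % of the intensity."""
    cfg = cd.SimulationConfig(seed=0, noise_sd=0.0, duration=180.0,
                              breathing_period=2.8,
                              modulation_depth_percent=dict(C2C3_DEPTHS),
                              phase_lag_deg=dict(C2C3_LAGS))
    flow, belt, _ = cd.generate_flow_record(cfg)
    _, _, cycles = cd.reconstruct(flow)
    res = cd.sweep_phase(cycles, cd.delineate_phases(belt))
    k = 28  # 2.8 s at the 0.1 s grid step
    for p in ("tc", "amplitude", "qnet"):
        dev = np.abs(res.curves[p][:-k] - res.curves[p][k:]).max()
        assert dev < 0.05 * res.effects[p].delta


def test_belt_shift_moves_curve():
    """Advancing the belt by +delta advances the Delta-p(Phi) curve by the
    same amount (so the recovered phase moves by -delta)."""
    cfg = cd.SimulationConfig(seed=0, noise_sd=0.0, duration=180.0,
                              modulation_depth_percent=dict(C2C3_DEPTHS),
                              phase_lag_deg=dict(C2C3_LAGS))
    flow, belt, _ = cd.generate_flow_record(cfg)
    _, _, cycles = cd.reconstruct(flow)
    res0 = cd.sweep_phase(cycles, cd.delineate_phases(belt))
    shifted = cosine_belt(duration=180.0, t_shift=0.5)
    res1 = cd.sweep_phase(cycles, cd.delineate_phases(shifted))
    k = 5  # 0.5 s = 5 grid steps
    for p in ("tc", "amplitude"):
        dev = np.abs(res1.curves[p][:-k] - res0.curves[p][k:]).max()
        assert dev < 0.10 * res0.effects[p].delta


def test_doubling_flow_scales_delta_not_percent(modulated_record):
    _, flow, belt, _ = modulated_record
    _, _, c1 = cd.reconstruct(flow)
    _, _, c2 = cd.reconstruct(cd.FlowSeries(flow.time, 2 * flow.flow))
    phases = cd.delineate_phases(belt)
    r1, r2 = cd.sweep_phase(c1, phases), cd.sweep_phase(c2, phases)
    for p in ("qnet", "amplitude"):
        assert r2.effects[p].delta == pytest.approx(
            2 * r1.effects[p].delta, rel=1e-6)
        assert r2.effects[p].delta_percent == pytest.approx(
            r1.effects[p].delta_percent, rel=1e-6)


def test_delta_at_zero_bounded_by_intensity(modulated_record):
    _, flow, belt, _ = modulated_record
    _, _, cycles = cd.reconstruct(flow)
    res = cd.sweep_phase(cycles, cd.delineate_phases(belt))
    for p in ("tc", "amplitude", "qnet", "sv"):
        e = res.effects[p]
        mid = (np.nanmax(res.curves[p]) + np.nanmin(res.curves[p])) / 2
        assert abs(e.delta_at_zero - mid) <= e.delta + 1e-12
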
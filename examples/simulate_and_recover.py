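"""Inject known breathing effects and recover them with the phase sweep.

Generates a free-breathing CSF record whose cardiac period, flow amplitude
and net flow are modulated at the breathing period with known depths and
phase lags (spinal-level magnitudes), then runs the full time-domain
analysis: beat segmentation, inspiration/expiration delineation from the
belt, and the -3 s..+3 s phase-shift sweep.
"""

import numpy as np

import csfdyn as cd

injected_depth = {"tc": 6.0, "amplitude": 6.8, "qnet": 6.3}    # percent
injected_lag = {"tc": -64.0, "amplitude": -11.0, "qnet": 33.0}  # degrees

n_records = 10  # a single 45 s record carries sizeable phase scatter
recovered = {p: [] for p in injected_depth}
phase = {p: [] for p in injected_depth}
for seed in range(n_records):
    cfg = cd.SimulationConfig(
        seed=seed,
        noise_sd=0.05 * 338.0,                # 5 % of the flow amplitude
        modulation_depth_percent=injected_depth,
        phase_lag_deg=injected_lag,
    )
    flow, belt, truth = cd.generate_flow_record(cfg)
    _, _, cycles = cd.reconstruct(flow)
    phases = cd.delineate_phases(belt)
    result = cd.sweep_phase(cycles, phases)
    for p in injected_depth:
        recovered[p].append(result.effects[p].delta_percent)
        phase[p].append(result.effects[p].phi_deg)

print(f"{len(cycles)} beats over {phases.n_complete_cycles} breathing "
      f"cycles per record (Tb = {phases.mean_breathing_period:.2f} s); "
      f"mean over {n_records} records:")
print(f"{'parameter':10s} {'injected':>18s} {'recovered':>22s}")
for p in ("tc", "amplitude", "qnet"):
    d = np.mean(recovered[p])
    ph = np.mean(phase[p])
    sd = np.std(phase[p])
    print(f"{p:10s} {injected_depth[p]:7.1f} % @ {injected_lag[p]:6.1f}d"
          f" {d:8.1f} % @ {ph:6.1f}d (sd {sd:4.1f})")
print("delta% is the inspiration-expiration contrast of each parameter "
      "(Qnet normalized by the amplitude); the phase is where in the "
      "breathing cycle the contrast peaks.")
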
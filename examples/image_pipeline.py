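"""From velocity maps to a calibrated flow signal.

Renders a synthetic flow record onto phase-contrast velocity maps with a
constant eddy-current-like offset and pixel noise, then runs the image
chain: pulsatility-based segmentation from a seed pixel, stationary-tissue
background correction, de-aliasing, and flow integration.
"""

import numpy as np

import csfdyn as cd

cfg = cd.SimulationConfig(seed=2, noise_sd=0.0)
flow, _, _ = cd.generate_flow_record(cfg)

img = cd.ImageRenderConfig(background_offset=0.3,      # cm/s bias
                           stationary_tissue_noise_sd=0.05)
series = cd.render_velocity_series(flow, img, seed=2)

mask = cd.segment_csf_roi(series, seed_pixel=(15, 15))
stationary = cd.select_stationary_region(series, mask)
corrected = cd.correct_background(series, stationary)
clean = cd.dealias(corrected)
recovered = cd.extract_flow(clean, mask)

rms = np.sqrt(np.mean((recovered.flow - flow.flow) ** 2))
rel = 100 * rms / np.sqrt(np.mean(flow.flow ** 2))
print(f"segmented lumen: {mask.segment_area:.0f} mm^2 "
      f"(true {img.roi_area:.0f} mm^2)")
print(f"background reference: {stationary.reference_velocity:.3f} cm/s "
      f"(injected offset {img.background_offset} cm/s)")
print(f"flow recovery: {rel:.2f} % relative RMS error over "
      f"{flow.time.size} frames")
print("the segmentation finds pixels whose velocity spectrum is dominated "
      "by the cardiac band; the stationary ring re-zeroes the velocity "
      "scale, removing the spurious flow a constant offset would add.")
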
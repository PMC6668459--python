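"""Reconstruct a Siemens-star phase target from a simulated acquisition.

Simulates one 51.2 um tile (scaled down from the 110 um production tile so
the script runs in seconds) under the 21 brightfield LEDs of a well's
segment, adds sensor noise with 10-frame averaging, runs EPRY and reads the
lateral resolution off the restored phase.
"""

import platefpm as pf
from platefpm.pipeline import run_star_tile

cfg = pf.OpticalConfig(tile_um=51.2)
result = run_star_tile(cfg, delta_z_um=0.0, seed=1, n_spoke_pairs=12, n_iters=20)

print(f"final reconstruction residual: {result.recon.residuals[-1]:.2e}")
print(f"calibrated star contrast threshold: {result.threshold:.2f}")
print(f"restored phase resolution: {result.report.resolution_um:.2f} um "
      f"(detection limited: {result.report.at_detection_limit})")
print(f"single-LED coherent limit would be {cfg.wavelength_um / (2 * cfg.na_obj):.2f} um; "
      "the synthetic aperture roughly halves it")
# Expected output: residual ~1e-3 (noise floor), resolution ~0.6 um —
# well below the 1.26 um the physical instrument certifies, because the
# simulated star carries no fabrication or alignment imperfections.
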
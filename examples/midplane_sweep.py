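"""Mid-plane detection from trigger counts and received amplitude.

Sweeps the element across the elevational beam and reports the per-frame
trigger count at each offset, the detectable range, and the localization
accuracy achievable by raising the trigger level to 90% of the maximum.
"""

import numpy as np

from activeecho import (
    AEDevice, Scene, detectable_range, localize_midplane, midplane_sweep,
    preset_probe,
)

probe = preset_probe("general")  # elevational beam sigma 3 mm
scene = Scene.empty()
dev = AEDevice(position=(0.0, 0.0, 0.04), rx_gain_db=19.0)

offsets = np.arange(-9e-3, 9.5e-3, 1e-3)
sweep = midplane_sweep(probe, scene, dev, offsets, repeats=3, seed=0)

print("offset (mm) | trigger count")
for off, n in zip(sweep.offsets_mm, sweep.count_mean):
    print(f"   {off:+5.1f}    |  {'#' * int(n)} {int(n)}")

est, _ = localize_midplane(sweep, "count")
print(f"\ncount-method mid-plane estimate: {est:+.2f} mm (true 0.00 mm)")
print(f"detectable range: +/-{detectable_range(sweep):.1f} mm from the mid-plane")

_, hw = localize_midplane(sweep, "amplitude-threshold@0.9")
print(
    f"90%-amplitude trigger level keeps the element within +/-{hw:.2f} mm\n"
    "of the mid-plane - the count peaks when the tool tip crosses the\n"
    "imaging plane, and a high trigger level turns that into sub-mm accuracy."
)
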
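"""Frequency modulation + template filtering: pull the AE signal out of
speckle.

The AE element fires at 9 MHz while the imaging pulse is 10 MHz.  The AE
waveform template is obtained by subtracting echo-off from echo-on RF, and
matched filtering then locates the AE packet against the tissue background.
"""

import numpy as np

from activeecho import (
    AEDevice, PhantomSpec, Scene, acquire_frame, acquire_template,
    make_phantom, preset_probe, template_filter, water,
)

probe = preset_probe("general", n_elements=64, lines_per_frame=64)
med = water()
scene = Scene(med, make_phantom(
    PhantomSpec(bounds=(0.019, 0.01, 0.05), density=30.0), seed=3
))
dev = AEDevice(position=(0.0, 0.0, 0.04), pulse_freq=9e6, pulse_cycles=8)

on, log = acquire_frame(probe, scene, dev)
off, _ = acquire_frame(probe, scene, dev.at(mode="off"))
tpl = acquire_template(on, off)
print(
    f"{log.count} triggers; template: {len(tpl)} samples "
    f"({len(tpl)/probe.fs*1e6:.2f} us) on line {tpl.line_index}"
)

corr = template_filter(on, tpl)
line, pos = np.unravel_index(np.argmax(corr), corr.shape)
depth_mm = med.assumed_c * pos / probe.fs / 2 * 1e3
print(
    f"correlation peak on line {line} at {depth_mm:.2f} mm "
    f"(element line {tpl.line_index}, 40.00 mm)\n"
    "the 9 MHz, long-duration AE pulse correlates with its own template far\n"
    "better than the 10 MHz speckle does, so the tool stands out even when\n"
    "its raw echo amplitude matches the background."
)
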
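"""Reconstruct one bead with ASM and PCOF and compare twin-image ringing.

A single 30 um bead with peak phase 2*pi is simulated, its hologram
rendered at z = 1 mm, and reconstructed two ways.  The numbers printed are
the recovered peak phase (ground truth: 2*pi ~ 6.283 rad) and the standard
deviation of the unwrapped phase away from the bead -- the twin-image
"ringing" that the phase-support constraint suppresses.
"""

import numpy as np
from scipy import ndimage

from pcof import (
    BeadPhantomSpec,
    GridSpec,
    make_bead_phantom,
    pcof_reconstruct,
    reconstruct_asm,
    render_hologram,
)

grid = GridSpec(nx=256, ny=256, pitch=1.55e-6, wavelength=525e-9)
obj = make_bead_phantom(BeadPhantomSpec(n_beads=1, seed=3), grid)
holo = render_hologram(obj, z=1e-3)

asm = reconstruct_asm(holo, grid, z=1e-3)
pcof = pcof_reconstruct(holo, grid, z=1e-3)

off_object = ~ndimage.binary_dilation(obj.phase > 0, iterations=10)
print(f"ground-truth peak phase : {obj.phase.max():.3f} rad")
for result in (asm, pcof):
    phi = result.phase.values
    print(
        f"{result.method:4s} peak {phi.max():.3f} rad | "
        f"background ringing std {phi[off_object].std():.4f} rad"
    )
print(
    "\nLower background std means less twin-image ringing; PCOF masks the\n"
    "off-support phase before re-synthesising the hologram, ASM does not."
)
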
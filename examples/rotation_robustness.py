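"""Transmission robustness under rotation of the cubic membrane.

Rotates the gyroid lattice 0-80 degrees about an axis perpendicular to
the propagation direction and measures, per angle, the total forward
transmitted energy and the flux through the central beam (on-axis disk
of radius R/4 at the zero-angle focus plane).  The total energy is
nearly orientation-independent (quasi-bandgap behaviour); the central
beam fluctuates much more.  Several minutes.
"""

import numpy as np

from mitolens import build_mitochondrion, reference_wall, rotation_sweep

model = build_mitochondrion(wall_stack=reference_wall())
sw = rotation_sweep(model, np.arange(0.0, 81.0, 10.0), wavelength=550.0,
                    spacing=28.0)
print(f"{'angle':>6} {'total energy':>13} {'central beam':>13}")
for a, e, c in zip(sw["angles_deg"], sw["total_energy"], sw["central_beam"]):
    print(f"{a:6.0f} {e:13.1f} {c:13.1f}")
print(f"\ntotal-energy variation  (max-min)/mean: {100 * sw['energy_variation']:.1f}%")
print(f"central-beam variation  (max-min)/mean: {100 * sw['central_variation']:.1f}%")
print(f"(central beam evaluated at the {sw['focus_plane_um']:.1f} um focus plane "
      "of the unrotated model)")
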
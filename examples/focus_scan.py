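"""Trace the default lens mitochondrion and scan for the focal plane.

Fires a dense plane-wave source (10 nm ray spacing, ~31,000 rays) at
600 nm through the default model, then propagates the exit field to
image planes 0.5-6 um behind the rear pole and reports where the peak
intensity is largest.  Takes a few minutes.
"""

import numpy as np

from mitolens import build_mitochondrion, find_focus, reference_wall
from mitolens.transport import SourceGrid, trace

model = build_mitochondrion(wall_stack=reference_wall())
grid = SourceGrid(spacing=10.0, wavelength=600.0)
records, ledger = trace(model, grid, epsilon=1e-5)
print(f"traced {ledger.input:.0f} rays -> {ledger.n_exit_records} exit packets; "
      f"forward {100 * ledger.exited_forward / ledger.input:.1f}%, "
      f"back-scattered {100 * ledger.exited_backward / ledger.input:.1f}%, "
      f"discarded {100 * ledger.discarded / ledger.input:.4f}%")

res = find_focus(model, 600.0, plane_range_um=(0.5, 6.0), step_um=0.1,
                 spacing=10.0, records=records)
print(f"best focus: {res.focus_um:.1f} um behind the rear pole "
      f"(peak {res.peak_intensity:.1f}, centred={res.centered})")
for p, v in zip(res.planes_um[::5], res.peaks[::5]):
    print(f"  {p:4.1f} um  peak {v:6.1f}")
print("\nPeak intensity is in per-pixel energy units of the captured "
      "coherent field; the maximum marks the interference focus.")
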